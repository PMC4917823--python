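"""Sensitivity of the 2100 projection to the species survival thresholds.

Scales every species' tipping elevation by +/-15% and reruns the process-rich
model across the scenarios, reporting the end-of-century vegetated area.
"""

import saltmarsh as sm

res = sm.sensitivity_tipping(frac=0.15)
print(res.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

up = res.delta_vegetated(0.15, "smm", "RCP85")
down = res.delta_vegetated(-0.15, "smm", "RCP85")
print(
    f"\nUnder RCP 8.5, raising every threshold 15% changes the 2100 vegetated\n"
    f"area by {up:+.3f} ha and lowering them changes it by {down:+.3f} ha:\n"
    f"the projection hinges on how much submergence the plants tolerate."
)
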