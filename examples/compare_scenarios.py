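"""Compare the process-rich marsh model against the inundation-only baseline.

Runs both models from 2008 to 2100 under no rise, the regional 0.30 m
projection (PSLR) and the IPCC RCP 8.5 max 0.98 m, on one synthetic shore,
and prints the signed change of total above-water habitat.
"""

import saltmarsh as sm

cfg = sm.RunConfig()  # default 200x200 shore, landscape seed 42
comp = sm.run_comparison(cfg)

print(f"{'model':<12} {'scenario':<8} {'2008 ha':>8} {'2100 ha':>8} {'change %':>9}")
for model in ("smm", "slamm-lite"):
    for scen in cfg.scenarios:
        rows = comp.changes
        row = rows[
            (rows.model == model)
            & (rows.scenario == scen)
            & (rows.period == "2008-2100")
            & (rows.habitat == "TOTAL")
        ].iloc[0]
        print(
            f"{model:<12} {scen:<8} {row.area_start_ha:>8.3f} "
            f"{row.area_end_ha:>8.3f} {row.signed_pct_change:>+9.2f}"
        )

print(
    "\nThe process-rich model (smm) grows habitat where sediment supply keeps\n"
    "pace with the sea and vegetation traps more of it; the decision-tree\n"
    "baseline (slamm-lite) can only lose ground because it has no lateral\n"
    "accretion or vegetative spread."
)
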