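# Methods

## Scope and frame

The package simulates the response of an estuarine salt marsh to sea-level
rise (SLR) on a gridded landscape, contrasting two models on identical
inputs: a process-rich cellular automaton (`smm`) coupling sedimentary and
vegetative dynamics, and a reduced inundation/accretion decision tree
(`slamm-lite`). All elevations are metres above a local bathymetric datum.
Every biological rule consumes the *relative* elevation
E_rel = E − offset(year): thresholds calibrated at the 2008 baseline stay
valid as the sea rises. Scenarios are endpoint-anchored (0, 0.30, 0.98 m by
2100); the trajectory shape is a knob (`linear` default, `quadratic`
offered because late-century acceleration is the projected pattern), since
only the endpoints are specified by the scenarios themselves.

## Species response curves

Survival over a growing season is a two-parameter logistic in elevation,
S(E) = 1/(1 + a·e^(−kE)), fitted by binomial maximum likelihood (a
logit-link GLM; least squares on fractions would discard the binomial
weighting of the counts). The tipping point P is located by scanning E at a
regular step *i* (default 0.01 m) and maximising the binary Shannon entropy
H(E) = −[S·ln S + (1−S)·ln(1−S)]; H is unimodal with its maximum at S = 0.5,
so P coincides with the analytic midpoint ln(a)/k to within one grid step.
The scan is retained (rather than just the closed form) because it
generalises to non-logistic survival profiles and provides the entropy
profile for inspection. Degenerate datasets — all survived, none survived,
or only 0/1 outcomes (complete separation) — raise a non-identifiability
error rather than returning an unbounded fit; a fitted non-positive slope
(survival *decreasing* with elevation) warns and flags the tipping point as
not meaningful.

Default parameters encode the fitted field thresholds: P = 1.9 m
(*S. mariqueter*), 2.5 m (*S. alterniflora*), 2.9 m (*P. australis*). The
steepness k is not species-resolved by the available estimates; the shared
default k = 8 m⁻¹ makes survival fall from 0.9 to 0.1 over ≈ 0.55 m,
consistent with the span of the transplant design (2.2–3.0 m). Seed setting
is linear in elevation, clipped to [0, 1]; the shipped lines reach 0 at P
and 1 at P + 1 m — a synthetic default, as no per-species table is
available.

The tide is idealised as one sinusoid: D(E_rel) = (24/π)·arccos(clamp((E_rel
− MSL)/A, −1, 1)) hours per day. Defaults MSL 2.0 m, amplitude 1.5 m (half a
3 m mean range, inside the reported 1.96–3.08 m average-range band) place
the three tipping elevations at ≈ 12.5, 9.4 and 7.1 h day⁻¹ of submergence,
near the field-estimated 13/10/8 h day⁻¹. Spring–neap modulation is
omitted; durations are diagnostics, survival depends on elevation directly.

## The annual automaton step

Fixed process order, one pass per year:

1. **Vertical budget.** ΔE (m) = 0.001·(base_rate · τ − subsidence), with
   base_rate the cell's accretion/erosion rate (mm yr⁻¹), τ the species
   trapping multiplier (SA 1.5, SM 1.2, PA 1.2; τ = 1 unvegetated or with
   the feedback off) and subsidence 1.5 mm yr⁻¹ by default. Subtidal cells
   accrete at the base rate (shoal growth; config flag, default on) — this
   is the source of lateral mudflat emergence. Units are converted from mm
   exactly once, here. Subsidence lowers the land while the datum stays
   fixed, so it never double-counts with the SLR offset.
2. **Waterline.** Mudflat with E_rel < 0 becomes water; water with
   E_rel ≥ 0 becomes mudflat. Vegetated cells below the waterline are left
   to mortality (their survival is ≈ 0), becoming mudflat first and water a
   year later — a one-year lag that keeps the rule local and simple.
3. **Mortality.** Each vegetated cell survives with probability S(E_rel).
4. **Seed rain.** Each vegetated cell emits fecundity × seed-setting-rate
   seeds, spread over a Moore window (radius 3 cells) by an exponential
   kernel (e-folding 2 m) normalised to sum 1 — deposition conserves the
   emitted mass except over the grid edge (absorbing boundary).
5. **Establishment.** A mudflat cell with seeds of a species whose band
   contains E_rel converts with probability 1 − (1 − g·S)^min(bank, cap):
   up to `cap` (10) seeds each germinate (g = 0.05) and survive their first
   year independently. Contested cells go to the higher competitive rank
   (PA > SA > SM, which enforces both the SA-over-SM overlap rule and PA's
   priority on the high band). Banks are zeroed on conversion and otherwise
   decay to 10% (near-annual turnover; persistence is not documented for
   these species, so the bank is deliberately short-lived).
6. **Clonal spread.** A mudflat cell with n occupied Moore-1 neighbours of
   a species converts with probability 1 − (1 − λ)^n (λ: SA 0.30, SM 0.25,
   PA 0.20), band permitting, simultaneously from the pre-step state.
7. **Competition.** An SM cell at SA-suitable elevation with an SA
   neighbour converts with probability 0.4 × S_SA(E_rel). The reverse
   transition needs no rule: when SLR drops a cell below the SA band,
   mortality clears SA and SM re-establishes — pioneer recolonisation is an
   emergent behaviour, not a coded transition.

Elevation must precede survival and reproduction precede establishment;
the rest of the order is a modelling choice and is config-visible. Runs are
stochastic with a seeded `numpy` generator (same seed ⇒ bit-identical
trajectories). An expected-value mode replaces each Bernoulli draw by its
p ≥ 0.5 threshold for exact fixed-point tests; it is a testing device, not
a calibrated deterministic model.

Establishment bands: SM [1.9, 2.6), SA [2.5, 10), PA [2.9, 10) m. Floors
sit at each species' tipping point (founding below it is demographically
futile); SM's ceiling slightly overhangs the SA floor so the pioneer can
seed the overlap zone before being outcompeted. Fecundity 100 seeds per
occupied cell is nominal — only the product fecundity × g × S is dynamically
meaningful.

## The decision-tree baseline

`slamm-lite` keeps the same vertical budget (base rate, no trapping) and
reclassifies each cell *downward only* when its E_rel falls below its
category's lower bound, to the band that now contains it. No upward
transfers: emergent high ground keeps its category, because the adjacency
rules that would govern upward conversion in the full decision-tree software
are not specified in our sources. Erosion, overwash and saturation are
likewise dropped; what the contrast needs is precisely the absence of
lateral/vegetative feedback. The accretion feedback curve of the original
software is unspecified in our sources, so the rate multiplier is 1
regardless of depth (flagged in config).

## Synthetic landscape

A 200 × 200 grid of 1 m cells (configurable; coarse 30 m cells are
supported for large scenes). Elevation is a south-to-north ramp from −2 m
(seaward edge) to +4 m plus a smoothed Gaussian field (σ 0.15 m,
correlation length 5 cells). Habitat is initialised from the elevation
bands, lower-inclusive; with zero noise the scene is exact horizontal
stripes. Accretion decays exponentially landward from 20 mm yr⁻¹ at the
seaward edge to 2 mm yr⁻¹ at the landward edge — deposition concentrates on
the frontier flats — plus a smoothed noise field (σ 2 mm yr⁻¹, same
correlation length) representing the patchy deposition/erosion mosaic of a
real sedimentary regime; a few frontier cells are therefore net-erosional,
which is what lets the baseline model lose habitat even under the low
scenario while the mean supply keeps the frontier ahead of the sea. The σ
was chosen from the drift balance (accretion − subsidence vs SLR rate), not
fitted to any outcome. The generator is a pure function of (spec, seed).

What the scene does **not** emulate: real deltaic geometry, tidal creeks,
seawalls ("coastal squeeze" is representable only as nodata masks),
hydrodynamic sediment routing, and any feedback of inundation time on the
deposition rate (the regime is a fixed map, as in the long-term-average
approach). Passing tests therefore demonstrate mechanism and direction —
resilience through lateral accretion, trapping and recolonisation — not
calibrated area forecasts for a real wetland.

The mesocosm generator draws survivors ~ Binomial(n, S(E; P, k)) and seed
fractions from the clipped line plus Gaussian noise (σ 0.05), at the
transplant design (3.0/2.5/2.2 m, 10 replicates) by default; parameter-
recovery tests use a denser design (1.5–3.5 m every 0.25 m, n = 200) where
the likelihood is well conditioned.

## Reporting

Change tables report signed percentages 100·(end − start)/start per habitat
against the 2008 baseline for the periods 2008–2025/2050/2100 (all periods
share the 2008 denominator), with a TOTAL row covering above-water habitat;
a habitat with zero start area gets a flagged (NaN) percentage. The
sensitivity operation scales every species' tipping elevation by (1 ± 15%) —
multiplicative, the natural reading for a threshold in metres — and reruns
the comparison; only the process-rich model responds, since the baseline
never consults survival.

## Numerical and degenerate-input choices

- Band boundaries lower-inclusive/upper-exclusive everywhere (a cell at
  exactly 2.5 m is SA).
- Nodata cells (NaN elevation / code 0) are excluded from every process and
  every area total.
- ASCII rasters round-trip bit-exactly for habitat codes and to 1e-6 m for
  reals; the first file row is the northernmost.
- The entropy scan clips S away from {0, 1} before taking logs; profiles
  are monotone to float precision on either side of the peak.
- A quasi-separated logistic (|slope| > 1e4) is treated as non-identifiable.
- Dispersal mass leaving the grid is lost (absorbing boundary).

## Problem sizes

Default experiments run the 200 × 200 scene for 92 years; a full two-model ×
three-scenario comparison takes ~5 s on one CPU, the ±15% sensitivity ~15 s,
and the ten-seed scenario-monotonicity check ~1 min. These sizes give
thousands of cells per habitat band, ample for the directional and
conservation properties the test suite asserts.

## Known limitations

- Annual time step: storm events, intra-annual tides and phenology are
  invisible; the survival logistic absorbs them implicitly.
- The accretion regime is static; real deposition responds to inundation
  duration and sediment load, both of which change with SLR.
- Morphological plasticity of the plants (stem elongation under flooding)
  is not modelled; thresholds are fixed per species.
- The clonal, germination, fecundity and invasion rates are stand-ins
  calibrated to qualitative behaviour (band-tracking, pioneer
  recolonisation, SA invasion), not to field demography.
- `slamm-lite` is not a numerical reproduction of any release of the SLAMM
  software.
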