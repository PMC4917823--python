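"""Annual cellular-automaton step and multi-year run of the marsh model.

Each simulation year applies, in fixed order:

1. the vertical sediment budget (accretion × vegetation trapping − subsidence),
   followed by reclassification across the waterline (emergent shoals become
   mudflat, drowned mudflat becomes open water);
2. inundation mortality — every vegetated cell survives the year with the
   species' elevation-logistic probability;
3. seed production and dispersal over a Moore neighbourhood with an
   exponential-decay kernel (mass-conserving away from the grid edge);
4. establishment of seeds on bare mudflat inside the species' elevation band;
5. clonal (rhizome/tiller) spread into adjacent bare mud;
6. interspecific competition: *S. alterniflora* invading the pioneer
   *S. mariqueter* zone where the elevation suits it.

All biological rules see the elevation *relative to the current sea surface*,
so a rising sea lowers every cell in the rules' frame.  Runs are stochastic
with a seeded generator (bit-reproducible); an expected-value mode replaces
every Bernoulli draw by its p ≥ 0.5 threshold for exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .forcing import (
    SLRScenario,
    SubsidenceModel,
    TidalRegime,
    TrappingParams,
    annual_elevation_update,
    sea_level_offset,
)
from .grids import (
    ElevationGrid,
    Habitat,
    HabitatGrid,
    SedimentRegimeGrid,
    habitat_areas,
    total_habitat_area,
    vegetated_area,
)
from .species import SpeciesParams, default_species_params, seed_setting_rate, survival_probability

__all__ = [
    "LandscapeState",
    "EngineConfig",
    "Forcing",
    "SimulationResult",
    "apply_mortality",
    "produce_and_disperse_seeds",
    "establish",
    "clonal_spread",
    "apply_competition",
    "step_year",
    "run_smm",
    "SNAPSHOT_YEARS",
]

SNAPSHOT_YEARS = (2025, 2050, 2100)


@dataclass
class LandscapeState:
    """Landscape at one simulation year: elevation, habitat and seed banks."""

    year: int
    elev: ElevationGrid
    hab: HabitatGrid
    seedbank: dict[Habitat, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for h, bank in self.seedbank.items():
            if bank.shape != self.elev.spec.shape:
                raise ValueError(f"seedbank for {h.name} has wrong shape")
            if np.any(bank < 0):
                raise ValueError("seed bank must be non-negative")

    def ensure_seedbanks(self, species: dict[Habitat, SpeciesParams]) -> None:
        for h in species:
            if h not in self.seedbank:
                self.seedbank[h] = np.zeros(self.elev.spec.shape)

    def copy(self) -> "LandscapeState":
        return LandscapeState(
            self.year,
            self.elev.copy(),
            self.hab.copy(),
            {h: b.copy() for h, b in self.seedbank.items()},
        )


@dataclass(frozen=True)
class EngineConfig:
    """Engine switches and numerical knobs.

    ``neighbourhood`` is the Moore radius (cells) of the dispersal kernel;
    clonal spread always uses radius 1.  ``seedbank_retention`` is the
    fraction of unused seeds carried to the next year (near-annual turnover
    by default).  ``establishment_cap`` bounds the number of seeds that can
    independently attempt establishment in one cell.  ``invasion_prob`` is
    the per-year probability scale of *S. alterniflora* overgrowing an
    *S. mariqueter* cell that has an SA neighbour and suitable elevation.
    """

    seed: int = 0
    neighbourhood: int = 3
    trapping_feedback: bool = True
    clonal: bool = True
    competition: bool = True
    stochastic: bool = True
    water_accretes: bool = True
    seedbank_retention: float = 0.1
    establishment_cap: float = 10.0
    invasion_prob: float = 0.4

    def __post_init__(self) -> None:
        if self.neighbourhood < 1:
            raise ValueError("Moore radius must be >= 1")
        if not 0.0 <= self.seedbank_retention <= 1.0:
            raise ValueError("seedbank_retention must lie in [0, 1]")


@dataclass(frozen=True)
class Forcing:
    """Abiotic forcing bundle shared by both models."""

    scenario: SLRScenario
    sediment: SedimentRegimeGrid
    tide: TidalRegime = TidalRegime()
    subsidence: SubsidenceModel = SubsidenceModel()

    def offset(self, year: float) -> float:
        return sea_level_offset(self.scenario, year)


def _trapping_from_species(species: dict[Habitat, SpeciesParams]) -> TrappingParams:
    return TrappingParams(
        sa=species[Habitat.SA].trapping,
        sm=species[Habitat.SM].trapping,
        pa=species[Habitat.PA].trapping,
    )


def _bernoulli(p: np.ndarray, rng: np.random.Generator | None, stochastic: bool) -> np.ndarray:
    if stochastic:
        return rng.random(p.shape) < p
    return p >= 0.5


def _by_rank(species: dict[Habitat, SpeciesParams]) -> list[SpeciesParams]:
    return sorted(species.values(), key=lambda sp: -sp.competitive_rank)


def _in_band(sp: SpeciesParams, e_rel: np.ndarray) -> np.ndarray:
    lo, hi = sp.establishment_band
    return (e_rel >= lo) & (e_rel < hi)


def reclassify_waterline(hab: HabitatGrid, e_rel: np.ndarray) -> HabitatGrid:
    """Move the water–mudflat boundary with relative elevation: drowned
    mudflat (E_rel < 0) becomes open water, emergent shoals become mudflat."""
    out = hab.copy()
    out.codes[(hab.codes == Habitat.MUDFLAT) & (e_rel < 0)] = Habitat.WATER
    out.codes[(hab.codes == Habitat.WATER) & (e_rel >= 0)] = Habitat.MUDFLAT
    return out


def apply_mortality(
    state: LandscapeState,
    species: dict[Habitat, SpeciesParams],
    e_rel: np.ndarray,
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
) -> LandscapeState:
    """Inundation mortality: vegetated cells survive w.p. S_sp(E_rel);
    non-survivors revert to bare mudflat."""
    out = state.copy()
    for sp in _by_rank(species):
        cells = state.hab.mask(sp.code)
        if not cells.any():
            continue
        s = survival_probability(sp, e_rel)
        dies = cells & ~_bernoulli(s, rng, stochastic)
        out.hab.codes[dies] = Habitat.MUDFLAT
    return out


def _dispersal_kernel(radius: int, decay_m: float, cell_size: float) -> np.ndarray:
    ax = np.arange(-radius, radius + 1) * cell_size
    dist = np.hypot(*np.meshgrid(ax, ax))
    kern = np.exp(-dist / decay_m)
    return kern / kern.sum()


def produce_and_disperse_seeds(
    state: LandscapeState,
    species: dict[Habitat, SpeciesParams],
    e_rel: np.ndarray,
    radius: int = 3,
) -> LandscapeState:
    """Seed rain: every vegetated cell emits fecundity × seed-setting-rate
    seeds, spread over the (2r+1)² Moore window by a normalised
    exponential-decay kernel.  Deposition conserves the emitted mass except
    where the window overhangs the grid edge (absorbing boundary)."""
    out = state.copy()
    out.ensure_seedbanks(species)
    cell = state.elev.spec.cell_size
    for sp in species.values():
        source = state.hab.mask(sp.code)
        if not source.any():
            continue
        emitted = np.where(source, sp.fecundity * seed_setting_rate(sp, e_rel), 0.0)
        kern = _dispersal_kernel(radius, sp.dispersal_decay, cell)
        out.seedbank[sp.code] += ndimage.convolve(emitted, kern, mode="constant", cval=0.0)
    return out


def establish(
    state: LandscapeState,
    species: dict[Habitat, SpeciesParams],
    e_rel: np.ndarray,
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
    cap: float = 10.0,
    retention: float = 0.1,
) -> LandscapeState:
    """Seed establishment on bare mudflat inside the species band.

    Conversion probability 1 − (1 − g·S)^min(seedbank, cap): each of up to
    ``cap`` seeds germinates and survives its first year independently.
    Contested cells go to the higher competitive rank.  Seed banks are
    consumed on conversion and otherwise decay by ``retention``.
    """
    out = state.copy()
    out.ensure_seedbanks(species)
    taken = np.zeros(state.hab.spec.shape, dtype=bool)
    mud = state.hab.mask(Habitat.MUDFLAT)
    for sp in _by_rank(species):
        bank = out.seedbank[sp.code]
        eligible = mud & ~taken & (bank > 0) & _in_band(sp, e_rel)
        if not eligible.any():
            continue
        g_s = np.clip(sp.germination_prob * survival_probability(sp, e_rel), 0.0, 1.0)
        p = 1.0 - np.power(1.0 - g_s, np.minimum(bank, cap))
        converts = eligible & _bernoulli(p, rng, stochastic)
        out.hab.codes[converts] = sp.code
        bank[converts] = 0.0
        taken |= converts
    for h in out.seedbank:
        out.seedbank[h] *= retention
    return out


_MOORE1 = np.ones((3, 3))
_MOORE1[1, 1] = 0.0


def clonal_spread(
    state: LandscapeState,
    species: dict[Habitat, SpeciesParams],
    e_rel: np.ndarray,
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
) -> LandscapeState:
    """Vegetative expansion: a bare-mud cell with n occupied Moore-1
    neighbours of a species converts w.p. 1 − (1 − λ)^n, elevation band
    permitting; simultaneous update from the pre-step state."""
    out = state.copy()
    mud = state.hab.mask(Habitat.MUDFLAT)
    taken = np.zeros(state.hab.spec.shape, dtype=bool)
    for sp in _by_rank(species):
        lam = sp.annual_clonal_prob
        if lam <= 0:
            continue
        n_adj = ndimage.convolve(
            state.hab.mask(sp.code).astype(float), _MOORE1, mode="constant", cval=0.0
        )
        p = 1.0 - np.power(1.0 - lam, np.round(n_adj))
        converts = mud & ~taken & (n_adj > 0.5) & _in_band(sp, e_rel)
        converts &= _bernoulli(p, rng, stochastic)
        out.hab.codes[converts] = sp.code
        taken |= converts
    return out


def apply_competition(
    state: LandscapeState,
    species: dict[Habitat, SpeciesParams],
    e_rel: np.ndarray,
    rng: np.random.Generator | None = None,
    stochastic: bool = True,
    invasion_prob: float = 0.4,
) -> LandscapeState:
    """*S. alterniflora* invasion of the *S. mariqueter* zone: an SM cell at
    SA-suitable elevation with ≥1 SA neighbour converts w.p.
    invasion_prob × S_SA(E_rel).  When rising seas push cells below the SA
    band, mortality — not competition — clears SA, and SM recolonises."""
    sa = species[Habitat.SA]
    out = state.copy()
    sm_cells = state.hab.mask(Habitat.SM)
    if not sm_cells.any():
        return out
    n_sa = ndimage.convolve(
        state.hab.mask(Habitat.SA).astype(float), _MOORE1, mode="constant", cval=0.0
    )
    p = invasion_prob * survival_probability(sa, e_rel)
    invaded = sm_cells & (n_sa > 0.5) & _in_band(sa, e_rel)
    invaded &= _bernoulli(p, rng, stochastic)
    out.hab.codes[invaded] = Habitat.SA
    return out


def step_year(
    state: LandscapeState,
    forcing: Forcing,
    species: dict[Habitat, SpeciesParams] | None = None,
    cfg: EngineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LandscapeState:
    """Advance the landscape by one year (fixed process order; see module doc)."""
    species = species or default_species_params()
    cfg = cfg or EngineConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    elev = annual_elevation_update(
        state.elev,
        state.hab,
        forcing.sediment,
        forcing.subsidence,
        _trapping_from_species(species),
        feedback=cfg.trapping_feedback,
        water_accretes=cfg.water_accretes,
    )
    year = state.year + 1
    e_rel = elev.values - forcing.offset(year)
    out = LandscapeState(year, elev, state.hab.copy(), {h: b.copy() for h, b in state.seedbank.items()})
    out.hab = reclassify_waterline(out.hab, e_rel)

    out = apply_mortality(out, species, e_rel, rng, cfg.stochastic)
    out = produce_and_disperse_seeds(out, species, e_rel, cfg.neighbourhood)
    out = establish(
        out, species, e_rel, rng, cfg.stochastic, cfg.establishment_cap, cfg.seedbank_retention
    )
    if cfg.clonal:
        out = clonal_spread(out, species, e_rel, rng, cfg.stochastic)
    if cfg.competition:
        out = apply_competition(out, species, e_rel, rng, cfg.stochastic, cfg.invasion_prob)
    return out


@dataclass
class SimulationResult:
    """Trajectory summary of one model run."""

    model: str
    scenario: SLRScenario
    series: pd.DataFrame  # per-year habitat areas (ha) + totals
    snapshots: dict[int, LandscapeState]
    final: LandscapeState

    def areas_at(self, year: int) -> dict[Habitat, float]:
        return habitat_areas(self.snapshots[year].hab)


def _series_row(state: LandscapeState) -> dict:
    areas = habitat_areas(state.hab)
    row = {"year": state.year}
    row.update({h.name: areas.get(h, 0.0) for h in Habitat})
    row["total_habitat"] = total_habitat_area(state.hab)
    row["vegetated"] = vegetated_area(state.hab)
    return row


def run_smm(
    initial: LandscapeState,
    end_year: int,
    scenario: SLRScenario,
    sediment: SedimentRegimeGrid,
    species: dict[Habitat, SpeciesParams] | None = None,
    cfg: EngineConfig | None = None,
    tide: TidalRegime | None = None,
    subsidence: SubsidenceModel | None = None,
    snapshot_years: tuple[int, ...] = SNAPSHOT_YEARS,
) -> SimulationResult:
    """Iterate the annual step from ``initial.year`` to ``end_year`` under one
    SLR scenario, retaining snapshots and a per-year area series."""
    species = species or default_species_params()
    cfg = cfg or EngineConfig()
    forcing = Forcing(
        scenario=scenario,
        sediment=sediment,
        tide=tide or TidalRegime(),
        subsidence=subsidence or SubsidenceModel(),
    )
    rng = np.random.default_rng(cfg.seed)
    state = initial.copy()
    state.ensure_seedbanks(species)
    rows = [_series_row(state)]
    snaps = {state.year: state.copy()} if state.year in snapshot_years else {}
    while state.year < end_year:
        state = step_year(state, forcing, species, cfg, rng)
        rows.append(_series_row(state))
        if state.year in snapshot_years:
            snaps[state.year] = state.copy()
    snaps.setdefault(state.year, state.copy())
    return SimulationResult(
        model="smm",
        scenario=scenario,
        series=pd.DataFrame(rows),
        snapshots=snaps,
        final=state,
    )
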