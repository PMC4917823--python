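"""Reduced decision-tree baseline: vertical inundation + accretion only.

This is the contrast model: land-cover categories are re-evaluated each year
against fixed elevation thresholds on the *relative* elevation, and a cell can
only move down the category ladder (PA/SA → SM → MUDFLAT → WATER) as the sea
overtakes it.  There is no seed dispersal, no clonal spread, no competition
and no vegetation–sediment trapping feedback, so the baseline cannot grow
marsh laterally — the mechanism whose absence the process-rich model exposes.
The run is fully deterministic.

The full SLAMM family of models also treats erosion, overwash and soil
saturation; those processes are intentionally out of scope here, which is why
the model is called "slamm-lite" in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Forcing, LandscapeState, SimulationResult, _series_row, SNAPSHOT_YEARS
from .forcing import (
    SLRScenario,
    SubsidenceModel,
    TidalRegime,
    annual_elevation_update,
)
from .grids import Habitat, SedimentRegimeGrid, ZonationScheme

__all__ = ["DecisionTree", "slamm_step", "run_slamm_lite"]


@dataclass(frozen=True)
class DecisionTree:
    """Category thresholds evaluated on relative elevation.

    Every category accretes at the base sedimentary rate (no species
    trapping).  ``water_accretes`` mirrors the process-rich model's shoal
    growth so both models share the same vertical budget; emergent ground
    still never re-enters a higher category (downward-only transfers).
    """

    zonation: ZonationScheme = ZonationScheme()
    water_accretes: bool = True


def slamm_step(
    state: LandscapeState,
    forcing: Forcing,
    tree: DecisionTree | None = None,
) -> LandscapeState:
    """One annual step: vertical budget, then downward-only reclassification."""
    tree = tree or DecisionTree()
    elev = annual_elevation_update(
        state.elev,
        state.hab,
        forcing.sediment,
        forcing.subsidence,
        feedback=False,
        water_accretes=tree.water_accretes,
    )
    year = state.year + 1
    e_rel = elev.values - forcing.offset(year)
    out = LandscapeState(year, elev, state.hab.copy(), {})
    band = tree.zonation.classify(e_rel).astype(np.int16)
    valid = state.hab.valid
    # downward-only: a cell adopts the band its relative elevation now sits in
    # only when that band ranks below its current category
    out.hab.codes[valid] = np.minimum(state.hab.codes[valid], band[valid])
    return out


def run_slamm_lite(
    initial: LandscapeState,
    end_year: int,
    scenario: SLRScenario,
    sediment: SedimentRegimeGrid,
    tree: DecisionTree | None = None,
    tide: TidalRegime | None = None,
    subsidence: SubsidenceModel | None = None,
    snapshot_years: tuple[int, ...] = SNAPSHOT_YEARS,
) -> SimulationResult:
    """Deterministic multi-year run of the decision-tree baseline."""
    tree = tree or DecisionTree()
    forcing = Forcing(
        scenario=scenario,
        sediment=sediment,
        tide=tide or TidalRegime(),
        subsidence=subsidence or SubsidenceModel(),
    )
    state = LandscapeState(initial.year, initial.elev.copy(), initial.hab.copy(), {})
    rows = [_series_row(state)]
    snaps = {state.year: state.copy()} if state.year in snapshot_years else {}
    while state.year < end_year:
        state = slamm_step(state, forcing, tree)
        rows.append(_series_row(state))
        if state.year in snapshot_years:
            snaps[state.year] = state.copy()
    snaps.setdefault(state.year, state.copy())
    return SimulationResult(
        model="slamm-lite",
        scenario=scenario,
        series=pd.DataFrame(rows),
        snapshots=snaps,
        final=state,
    )
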