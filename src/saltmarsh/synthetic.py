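"""Seeded generators for synthetic estuarine landscapes and mesocosm data.

The landscape generator emulates a prograding estuarine shore: a linear ramp
from subtidal depths at the seaward (southern) edge to high marsh landward,
with smoothed Gaussian microtopography, and a sediment-supply field that is
strongest on the frontier flats and decays landward.  A second smoothed noise
field on the accretion rate represents the patchy deposition/erosion mosaic
of a real sedimentary regime; without it the vertical budget would be
spatially monotone and no frontier cell could ever fall behind the sea.

Habitat is initialised from the elevation bands (water < 0 m < mudflat <
2.0 m < *S. mariqueter* < 2.5 m < *S. alterniflora* < 2.9 m < *P. australis*),
so a noiseless ramp yields exact horizontal habitat stripes.

The mesocosm generator draws binomial survival counts from the survival
logistic and noisy linear seed-setting fractions, mirroring the transplant
experiment design (three elevations, 10 replicates per species by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .engine import LandscapeState
from .grids import (
    ElevationGrid,
    GridSpec,
    HabitatGrid,
    SedimentRegimeGrid,
    ZonationScheme,
    classify_initial_habitat,
)
from .species import MesocosmDataset

__all__ = ["LandscapeSpec", "make_landscape", "make_initial_state", "make_mesocosm_dataset"]

DEFAULT_MESOCOSM_ELEVATIONS = (3.0, 2.5, 2.2)  # m, the transplant design
DEFAULT_MESOCOSM_REPLICATES = 10


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the synthetic shore.

    The ramp runs south→north (last grid row is the seaward edge) from
    ``elev_min`` to ``elev_max``.  Elevation noise is a Gaussian field
    smoothed to ``noise_corr_cells`` and rescaled to ``noise_sigma`` (m).
    The accretion field decays exponentially landward from ``accr_max`` and
    hits ``accr_min`` exactly at the landward edge, plus a smoothed noise
    component of standard deviation ``accr_sigma`` (mm yr⁻¹) that creates
    local deposition hot spots and mildly erosional patches.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 1.0
    elev_min: float = -2.0
    elev_max: float = 4.0
    noise_sigma: float = 0.15
    noise_corr_cells: float = 5.0
    accr_max: float = 20.0
    accr_min: float = 2.0
    accr_sigma: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.elev_min >= self.elev_max:
            raise ValueError("elev_min must be below elev_max")
        if self.noise_sigma < 0 or self.accr_sigma < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.accr_max <= self.accr_min:
            raise ValueError("accr_max must exceed accr_min")


def _smoothed_noise(
    rng: np.random.Generator, shape: tuple[int, int], sigma: float, corr: float
) -> np.ndarray:
    """Gaussian field smoothed to a correlation length and rescaled so that
    the marginal standard deviation equals ``sigma``."""
    if sigma == 0:
        return np.zeros(shape)
    raw = rng.standard_normal(shape)
    if corr > 0:
        raw = ndimage.gaussian_filter(raw, corr, mode="reflect")
        raw /= raw.std()
    return sigma * raw


def make_landscape(
    spec: LandscapeSpec | None = None,
    zonation: ZonationScheme | None = None,
) -> tuple[ElevationGrid, HabitatGrid, SedimentRegimeGrid]:
    """Generate (elevation, habitat, accretion-rate) grids; pure in (spec, seed)."""
    spec = spec or LandscapeSpec()
    rng = np.random.default_rng(spec.seed)
    gspec = GridSpec(spec.n_rows, spec.n_cols, spec.cell_size)

    # row 0 is north (landward); distance from the seaward edge in cells
    row = np.arange(spec.n_rows, dtype=float)[:, None]
    d_max = max(spec.n_rows - 1, 1)
    d_sea = (spec.n_rows - 1) - row  # 0 at the seaward (last) row
    ramp = spec.elev_min + (spec.elev_max - spec.elev_min) * (d_sea / d_max)
    elev_values = np.broadcast_to(ramp, gspec.shape).copy()
    elev_values += _smoothed_noise(rng, gspec.shape, spec.noise_sigma, spec.noise_corr_cells)
    elev = ElevationGrid(gspec, elev_values)

    # exponential landward decay pinned to accr_min at the landward edge
    ratio = spec.accr_max / max(spec.accr_min, 1e-12)
    if ratio > 1.0 + 1e-9:
        profile = spec.accr_max * np.exp(-d_sea / (d_max / np.log(ratio)))
    else:
        profile = np.full_like(d_sea, spec.accr_max)
    accr = np.broadcast_to(profile, gspec.shape).copy()
    accr += _smoothed_noise(rng, gspec.shape, spec.accr_sigma, spec.noise_corr_cells)
    sed = SedimentRegimeGrid(gspec, accr)

    hab = classify_initial_habitat(elev, zonation or ZonationScheme())
    return elev, hab, sed


def make_initial_state(
    spec: LandscapeSpec | None = None,
    year: int = 2008,
    zonation: ZonationScheme | None = None,
) -> tuple[LandscapeState, SedimentRegimeGrid]:
    """Convenience: a ready-to-run landscape state plus its sediment regime."""
    elev, hab, sed = make_landscape(spec, zonation)
    return LandscapeState(year=year, elev=elev, hab=hab, seedbank={}), sed


def make_mesocosm_dataset(
    true_p: float,
    true_k: float = 8.0,
    elevations=DEFAULT_MESOCOSM_ELEVATIONS,
    n_reps: int = DEFAULT_MESOCOSM_REPLICATES,
    seed: int = 0,
    species: str = "synthetic",
    seed_line: tuple[float, float] | None = None,
    seed_noise_sd: float = 0.05,
) -> MesocosmDataset:
    """Draw a synthetic transplant experiment from known response curves.

    Survivors per elevation are Binomial(n_reps, S(E; P, k)) with
    S = 1/(1+exp(−k(E−P))); seed-setting fractions follow the linear model
    clip(c0 + c1·E, 0, 1) plus Gaussian noise (defaults: zero at the tipping
    point, one a metre above it).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    elev = np.asarray(elevations, dtype=float)
    s = 1.0 / (1.0 + np.exp(-true_k * (elev - true_p)))
    survived = rng.binomial(n_reps, s)
    c0, c1 = seed_line if seed_line is not None else (-true_p, 1.0)
    seed_frac = np.clip(c0 + c1 * elev + rng.normal(0, seed_noise_sd, elev.shape), 0, 1)
    return MesocosmDataset(
        species=species,
        elevation_m=elev,
        n_total=np.full(elev.shape, n_reps, dtype=int),
        n_survived=survived,
        seed_setting_fraction=seed_frac,
    )
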