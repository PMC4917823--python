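"""Gridded landscape containers, ESRI ASCII raster I/O, zonation and area accounting.

Elevations are metres above a local bathymetric datum (default "Wusong", the
benchmark used for the Yangtze Estuary); habitat is one of five categories
ordered by the elevation band each occupies:

    WATER < MUDFLAT < SM (*Scirpus mariqueter*) < SA (*Spartina alterniflora*)
          < PA (*Phragmites australis*)

Rasters travel as ESRI ASCII grids (.asc); the first data row is the
northernmost row, and every neighbourhood operation elsewhere in the package
relies on that orientation.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Habitat",
    "GridSpec",
    "ElevationGrid",
    "HabitatGrid",
    "SedimentRegimeGrid",
    "ZonationScheme",
    "GridFormatError",
    "read_ascii_grid",
    "write_ascii_grid",
    "classify_initial_habitat",
    "habitat_areas",
    "total_habitat_area",
    "vegetated_area",
    "areas_to_frame",
]

M2_PER_HA = 10_000.0


class Habitat(enum.IntEnum):
    """Habitat category codes; integer order follows the elevation bands."""

    WATER = 1
    MUDFLAT = 2
    SM = 3  # Scirpus mariqueter, pioneer of the low flats
    SA = 4  # Spartina alterniflora, introduced mid-marsh dominant
    PA = 5  # Phragmites australis, high-marsh dominant


VEGETATED = (Habitat.SM, Habitat.SA, Habitat.PA)


class GridFormatError(ValueError):
    """Raised when an ESRI ASCII grid file cannot be parsed."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: shape, cell size (m) and lower-left origin."""

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size**2


def _check_shape(spec: GridSpec, values: np.ndarray) -> None:
    if values.shape != spec.shape:
        raise ValueError(f"values shape {values.shape} != spec shape {spec.shape}")


@dataclass
class ElevationGrid:
    """Per-cell elevation in metres above the datum; NaN marks nodata."""

    spec: GridSpec
    values: np.ndarray
    datum_name: str = "Wusong"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_shape(self.spec, self.values)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def copy(self) -> "ElevationGrid":
        return ElevationGrid(self.spec, self.values.copy(), self.datum_name)


@dataclass
class SedimentRegimeGrid:
    """Per-cell vertical accretion (+) / erosion (−) rate, mm per year."""

    spec: GridSpec
    base_rate: np.ndarray

    def __post_init__(self) -> None:
        self.base_rate = np.asarray(self.base_rate, dtype=float)
        _check_shape(self.spec, self.base_rate)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.base_rate)


@dataclass
class HabitatGrid:
    """Per-cell habitat category; 0 marks nodata cells."""

    spec: GridSpec
    codes: np.ndarray

    NODATA_CODE = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        _check_shape(self.spec, self.codes)
        valid = self.codes != self.NODATA_CODE
        known = np.isin(self.codes[valid], [int(h) for h in Habitat])
        if not known.all():
            bad = np.unique(self.codes[valid][~known])
            raise ValueError(f"habitat codes outside the alphabet: {bad.tolist()}")

    @property
    def valid(self) -> np.ndarray:
        return self.codes != self.NODATA_CODE

    def mask(self, habitat: Habitat) -> np.ndarray:
        return self.codes == int(habitat)

    def copy(self) -> "HabitatGrid":
        return HabitatGrid(self.spec, self.codes.copy())


@dataclass(frozen=True)
class ZonationScheme:
    """Ordered elevation bands: (habitat, lower bound in m), lower-inclusive.

    The first band is open below; bounds must be strictly increasing so the
    bands tile the whole real line.  Defaults follow the estuarine shore
    profile: subtidal water below the 0 m isobath, bare mudflat to 2.0 m,
    *S. mariqueter* 2.0–2.5 m, *S. alterniflora* 2.5–2.9 m and *P. australis*
    above 2.9 m.
    """

    bands: tuple[tuple[Habitat, float], ...] = (
        (Habitat.WATER, -np.inf),
        (Habitat.MUDFLAT, 0.0),
        (Habitat.SM, 2.0),
        (Habitat.SA, 2.5),
        (Habitat.PA, 2.9),
    )

    def __post_init__(self) -> None:
        bounds = [b for _, b in self.bands]
        if not all(a < b for a, b in zip(bounds, bounds[1:])):
            raise ValueError("band lower bounds must be strictly increasing")

    @property
    def codes(self) -> np.ndarray:
        return np.array([int(h) for h, _ in self.bands], dtype=np.int16)

    @property
    def inner_bounds(self) -> np.ndarray:
        # bounds above the open-below first band
        return np.array([b for _, b in self.bands[1:]], dtype=float)

    def classify(self, elevation: np.ndarray) -> np.ndarray:
        """Vectorised band lookup (lower-inclusive / upper-exclusive)."""
        idx = np.searchsorted(self.inner_bounds, elevation, side="right")
        return self.codes[idx]

    def lower_bound(self, habitat: Habitat) -> float:
        for h, b in self.bands:
            if h == habitat:
                return b
        raise KeyError(habitat)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _parse_header(lines: list[str], path: Path) -> tuple[GridSpec, int]:
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"{path}: bad header line {line!r}") from exc
        else:
            break
    else:
        i += 1
    missing = [k for k in _HEADER_KEYS[:5] if k not in header]
    if missing:
        raise GridFormatError(f"{path}: missing header keys {missing}")
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        nodata_value=header.get("nodata_value", -9999.0),
    )
    return spec, i


def read_ascii_grid(path: str | Path, kind: str = "elevation"):
    """Read an ESRI ASCII grid as the declared content ``kind``.

    kind: "elevation" -> ElevationGrid, "sediment" -> SedimentRegimeGrid,
    "habitat" -> HabitatGrid.  The first data row is the northernmost row.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    spec, start = _parse_header(lines, path)
    rows: list[list[float]] = []
    for line in lines[start:]:
        if not line.strip():
            continue
        try:
            rows.append([float(t) for t in line.split()])
        except ValueError as exc:
            raise GridFormatError(f"{path}: non-numeric data token") from exc
    if len(rows) != spec.n_rows:
        raise GridFormatError(
            f"{path}: expected {spec.n_rows} data rows, found {len(rows)}"
        )
    for r in rows:
        if len(r) != spec.n_cols:
            raise GridFormatError(
                f"{path}: data row of {len(r)} values, header declares {spec.n_cols}"
            )
    values = np.array(rows, dtype=float)
    nodata = values == spec.nodata_value
    if kind == "habitat":
        codes = values.astype(np.int16)
        codes[nodata] = HabitatGrid.NODATA_CODE
        return HabitatGrid(spec, codes)
    values[nodata] = np.nan
    if kind == "elevation":
        return ElevationGrid(spec, values)
    if kind == "sediment":
        return SedimentRegimeGrid(spec, values)
    raise ValueError(f"unknown grid kind {kind!r}")


def write_ascii_grid(grid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (north-up, 6 significant digits)."""
    path = Path(path)
    spec: GridSpec = grid.spec
    if isinstance(grid, HabitatGrid):
        values = grid.codes.astype(float)
        values[~grid.valid] = spec.nodata_value
        fmt = "%d"
    else:
        values = np.array(
            grid.values if isinstance(grid, ElevationGrid) else grid.base_rate,
            dtype=float,
        )
        values = np.where(np.isnan(values), spec.nodata_value, values)
        fmt = "%.6f"
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.x_origin:.6f}\n"
        f"yllcorner {spec.y_origin:.6f}\n"
        f"cellsize {spec.cell_size:.6f}\n"
        f"NODATA_value {spec.nodata_value:g}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


HABITAT_CODE_SIDECAR = {h.name: int(h) for h in Habitat}


def write_habitat_sidecar(path: str | Path) -> None:
    """Write the habitat code mapping next to a raster (``<raster>.json``)."""
    Path(path).write_text(json.dumps(HABITAT_CODE_SIDECAR, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Classification and area accounting
# ---------------------------------------------------------------------------


def classify_initial_habitat(
    elev: ElevationGrid, zonation: ZonationScheme | None = None
) -> HabitatGrid:
    """Assign every cell the habitat band containing its elevation."""
    zonation = zonation or ZonationScheme()
    codes = zonation.classify(np.nan_to_num(elev.values, nan=0.0))
    codes = codes.astype(np.int16)
    codes[~elev.valid] = HabitatGrid.NODATA_CODE
    return HabitatGrid(elev.spec, codes)


def habitat_areas(hab: HabitatGrid) -> dict[Habitat, float]:
    """Area per habitat in hectares (cell count × cell area); nodata excluded."""
    cell_ha = hab.spec.cell_area_m2 / M2_PER_HA
    counts = np.bincount(hab.codes[hab.valid].ravel(), minlength=len(Habitat) + 1)
    return {h: counts[int(h)] * cell_ha for h in Habitat if counts[int(h)] > 0}


def total_habitat_area(hab: HabitatGrid) -> float:
    """Total marsh habitat above the waterline (mudflat + vegetation), ha."""
    areas = habitat_areas(hab)
    return sum(a for h, a in areas.items() if h != Habitat.WATER)


def vegetated_area(hab: HabitatGrid) -> float:
    """Total vegetated area (SM + SA + PA), ha."""
    areas = habitat_areas(hab)
    return sum(areas.get(h, 0.0) for h in VEGETATED)


def areas_to_frame(areas: dict[Habitat, float]) -> pd.DataFrame:
    """Area table with columns habitat, area_ha."""
    return pd.DataFrame(
        {"habitat": [h.name for h in areas], "area_ha": list(areas.values())}
    )
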