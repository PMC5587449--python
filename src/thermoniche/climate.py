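"""Monthly temperature rasters and per-locality thermal profiles.

A :class:`RasterStack` holds 12 monthly minimum-temperature grids and 12
monthly maximum-temperature grids on a common geotransform.  For each
locality the stack yields a :class:`ThermalProfile`:

* ``t_cold`` — the coldest monthly minimum at the containing cell, and
* ``t_hot`` — the *minimum* of the 12 monthly maxima at that cell, a
  conservative proxy for the warm temperatures a nocturnal animal actually
  experiences (day-time maxima are never met inside a roost).

Grids are read from ESRI ASCII format (``.asc``).  The WorldClim v1 dialect
stores temperatures as integers in tenths of a degree; ``scale`` converts
stored units to °C (0.1 for that dialect, 1.0 for grids already in °C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ExtentError, FormatError, MissingDataError
from .occurrences import LocalityRecord

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass(frozen=True)
class GridSpec:
    """Geotransform of a north-up regular grid (ESRI ASCII conventions)."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float

    @property
    def xmax(self) -> float:
        return self.xllcorner + self.ncols * self.cellsize

    @property
    def ymax(self) -> float:
        return self.yllcorner + self.nrows * self.cellsize

    def cell_index(self, longitude: float, latitude: float) -> tuple[int, int]:
        """Row/col of the cell containing a point (half-open cell intervals).

        A point exactly on the left/bottom edge of a cell belongs to that
        cell; the grid's outer right/top edges are exclusive.
        """
        if not (self.xllcorner <= longitude < self.xmax) or not (
            self.yllcorner <= latitude < self.ymax
        ):
            raise ExtentError(
                f"point ({longitude}, {latitude}) outside grid extent "
                f"[{self.xllcorner}, {self.xmax}) x [{self.yllcorner}, {self.ymax})"
            )
        col = int(math.floor((longitude - self.xllcorner) / self.cellsize))
        row = int(math.floor((self.ymax - latitude) / self.cellsize))
        # guard against the ymax boundary mapping to row == nrows
        col = min(col, self.ncols - 1)
        row = min(row, self.nrows - 1)
        return row, col


@dataclass
class RasterStack:
    """24 monthly temperature grids (12 minima then 12 maxima), in °C."""

    tmin: np.ndarray  # (12, nrows, ncols), °C, NaN where nodata
    tmax: np.ndarray  # (12, nrows, ncols), °C, NaN where nodata
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.tmin.shape != self.tmax.shape or self.tmin.shape[0] != 12:
            raise FormatError(
                f"expected two (12, nrows, ncols) stacks, got {self.tmin.shape} / {self.tmax.shape}"
            )
        if self.tmin.shape[1:] != (self.grid.nrows, self.grid.ncols):
            raise FormatError("grid shape disagrees with geotransform header")


@dataclass(frozen=True)
class ThermalProfile:
    """One locality's cold/hot temperature summary."""

    locality: LocalityRecord
    t_cold: float  # coldest monthly minimum, °C
    t_hot: float  # minimum of the monthly maxima, °C

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_cold) and math.isfinite(self.t_hot)):
            raise ValueError("profile temperatures must be finite")
        if self.t_cold > self.t_hot:
            raise ValueError(f"t_cold {self.t_cold} > t_hot {self.t_hot}")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float | None]:
    """Read one ESRI ASCII grid; returns (values, grid spec, nodata value).

    Values are returned exactly as stored (no scaling); rows run north to
    south as in the file.
    """
    header: dict[str, float] = {}
    nodata: float | None = None
    with open(path) as fh:
        pos = fh.tell()
        n_header = 0
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                key = parts[0].lower()
                if key == "nodata_value":
                    nodata = float(parts[1])
                else:
                    header[key] = float(parts[1])
                n_header += 1
            else:
                fh.seek(pos)
                break
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise FormatError(f"{path}: missing header keys {missing}")
        data = np.loadtxt(fh, dtype=float)
    spec = GridSpec(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    data = np.atleast_2d(data)
    if data.shape != (spec.nrows, spec.ncols):
        raise FormatError(f"{path}: data shape {data.shape} != header ({spec.nrows}, {spec.ncols})")
    return data, spec, nodata


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    nodata: float = -9999.0,
    fmt: str = "%.6g",
) -> None:
    """Write one grid in ESRI ASCII format (NaNs become the nodata value)."""
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
            f"xllcorner {grid.xllcorner!r}\nyllcorner {grid.yllcorner!r}\n"
            f"cellsize {grid.cellsize!r}\nNODATA_value {nodata!r}\n"
        )
        np.savetxt(fh, out, fmt=fmt)


def read_raster_stack(
    tmin_paths: Sequence[str | Path],
    tmax_paths: Sequence[str | Path],
    scale: float = 0.1,
    nodata: float | None = None,
) -> RasterStack:
    """Assemble 12+12 monthly grids into a stack, applying the storage scale.

    ``scale`` is °C per stored unit: 0.1 for WorldClim v1 integer grids
    (stored as °C × 10), 1.0 for grids already in °C. ``nodata`` overrides
    the per-file header value when given.
    """
    if len(tmin_paths) != 12 or len(tmax_paths) != 12:
        raise FormatError("expected 12 minimum and 12 maximum temperature grids")
    if scale <= 0:
        raise FormatError("scale factor must be > 0")

    def load(paths: Sequence[str | Path]) -> tuple[np.ndarray, GridSpec]:
        layers = []
        spec0: GridSpec | None = None
        for p in paths:
            vals, spec, nd = read_ascii_grid(p)
            if spec0 is None:
                spec0 = spec
            elif spec != spec0:
                raise FormatError(f"{p}: grid geometry differs from first layer")
            nd_eff = nodata if nodata is not None else nd
            vals = vals.astype(float)
            if nd_eff is not None:
                vals[vals == nd_eff] = np.nan
            layers.append(vals * scale)
        assert spec0 is not None
        return np.stack(layers), spec0

    tmin, spec_a = load(tmin_paths)
    tmax, spec_b = load(tmax_paths)
    if spec_a != spec_b:
        raise FormatError("minimum and maximum stacks have different geometries")
    return RasterStack(tmin=tmin, tmax=tmax, grid=spec_a)


def extract_profile(stack: RasterStack, locality: LocalityRecord) -> ThermalProfile:
    """Thermal profile at the cell containing the locality (no interpolation).

    Raises :class:`ExtentError` outside the grid and
    :class:`MissingDataError` when any of the 24 bands is nodata at the
    cell — callers exclude such localities and report them.
    """
    row, col = stack.grid.cell_index(locality.longitude, locality.latitude)
    minima = stack.tmin[:, row, col]
    maxima = stack.tmax[:, row, col]
    if np.isnan(minima).any() or np.isnan(maxima).any():
        raise MissingDataError(
            f"nodata at cell ({row}, {col}) for locality "
            f"({locality.longitude}, {locality.latitude})"
        )
    return ThermalProfile(
        locality=locality, t_cold=float(minima.min()), t_hot=float(maxima.min())
    )


def extract_profiles(
    stack: RasterStack, localities
) -> tuple[list[ThermalProfile], list[LocalityRecord]]:
    """Vector version of :func:`extract_profile`.

    Returns (profiles, excluded) where ``excluded`` lists localities outside
    the extent or over nodata cells.
    """
    profiles: list[ThermalProfile] = []
    excluded: list[LocalityRecord] = []
    for rec in localities:
        try:
            profiles.append(extract_profile(stack, rec))
        except (ExtentError, MissingDataError):
            excluded.append(rec)
    return profiles, excluded
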