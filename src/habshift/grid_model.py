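"""Raster data model and I/O for the habitat pipeline.

Everything spatial in this package moves through :class:`Grid`: a single-band
raster on a projected equal-area coordinate system, row 0 at the north edge,
column 0 at the west edge. Coordinates are kilometres; the cell area in km²
is exactly ``cell_size_km ** 2``. Inputs are expected to arrive already on a
common grid — the reader never resamples, and :func:`assert_aligned` rejects
stacks whose layers disagree on geometry.

Supported external formats: ESRI ASCII grid (read/write), CSV point tables
with an ``x,y`` header, and GeoJSON polygon collections (parsed in
:mod:`habshift.reserve_gap`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "GridGeometry",
    "GridStack",
    "GridFormatError",
    "AlignmentError",
    "read_grid",
    "write_grid",
    "assert_aligned",
    "cell_of",
    "cell_center",
    "area_km2",
    "read_points_csv",
    "write_points_csv",
]

#: relative tolerance for geometry comparisons (cell size, origin)
GEOMETRY_RTOL = 1e-6


class GridFormatError(ValueError):
    """A raster file violates the expected dialect."""


class AlignmentError(ValueError):
    """Layers that must share a geometry do not."""


@dataclass(frozen=True)
class GridGeometry:
    """Shared shape/placement descriptor of one or more grids.

    ``origin_xy`` is the outer (north-west) corner of cell (0, 0) in
    projected km; rows run north to south, columns west to east.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float
    origin_xy: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) outer bounds in km."""
        x0, y0 = self.origin_xy
        return (
            x0,
            y0 - self.n_rows * self.cell_size_km,
            x0 + self.n_cols * self.cell_size_km,
            y0,
        )

    def matches(self, other: "GridGeometry") -> bool:
        if self.shape != other.shape:
            return False
        scale = max(abs(self.cell_size_km), abs(other.cell_size_km), 1.0)
        tol = GEOMETRY_RTOL * scale
        return (
            abs(self.cell_size_km - other.cell_size_km) <= tol
            and abs(self.origin_xy[0] - other.origin_xy[0]) <= tol
            and abs(self.origin_xy[1] - other.origin_xy[1]) <= tol
        )


@dataclass
class Grid:
    """A single-band raster with an explicit nodata mask.

    ``values`` holds layer units as float64; ``nodata_mask`` is True where a
    cell carries no data. Derived layers must propagate nodata: a cell is
    valid only where every contributing input is valid.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    cell_size_km: float
    origin_xy: tuple[float, float]
    layer_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")
        self.origin_xy = (float(self.origin_xy[0]), float(self.origin_xy[1]))

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(
            n_rows=self.values.shape[0],
            n_cols=self.values.shape[1],
            cell_size_km=self.cell_size_km,
            origin_xy=self.origin_xy,
        )

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def with_values(self, values: np.ndarray, layer_name: str | None = None) -> "Grid":
        """Same geometry and mask, new cell values."""
        return Grid(
            values=values,
            nodata_mask=self.nodata_mask.copy(),
            cell_size_km=self.cell_size_km,
            origin_xy=self.origin_xy,
            layer_name=self.layer_name if layer_name is None else layer_name,
        )

    def masked(self) -> np.ndarray:
        """Values with nodata as NaN (copy)."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out


def area_km2(mask: np.ndarray, cell_size_km: float) -> float:
    """Exact area of the True cells: count × cell_size_km²."""
    return float(np.count_nonzero(mask)) * cell_size_km**2


class GridStack:
    """An ordered, named collection of co-registered grids.

    A cell is valid only if it is valid in every layer.
    """

    def __init__(self, layers: Mapping[str, Grid] | None = None):
        self._layers: dict[str, Grid] = {}
        if layers:
            for name, grid in layers.items():
                self.add(name, grid)

    def add(self, name: str, grid: Grid) -> None:
        if self._layers:
            ref = next(iter(self._layers.values())).geometry
            if not ref.matches(grid.geometry):
                raise AlignmentError(
                    f"layer {name!r} does not align with the stack geometry"
                )
        self._layers[name] = Grid(
            values=grid.values,
            nodata_mask=grid.nodata_mask,
            cell_size_km=grid.cell_size_km,
            origin_xy=grid.origin_xy,
            layer_name=name,
        )

    def __getitem__(self, name: str) -> Grid:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def geometry(self) -> GridGeometry:
        if not self._layers:
            raise ValueError("empty stack has no geometry")
        return next(iter(self._layers.values())).geometry

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.geometry.shape, dtype=bool)
        for g in self._layers.values():
            mask &= g.valid_mask
        return mask

    def subset(self, names: list[str]) -> "GridStack":
        return GridStack({n: self._layers[n] for n in names})

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> pd.DataFrame:
        """Layer values at (row, col) cell indices, one column per layer."""
        data = {name: g.values[rows, cols] for name, g in self._layers.items()}
        return pd.DataFrame(data)


def assert_aligned(stack: GridStack) -> GridGeometry:
    """Return the shared geometry, or raise naming the deviating layer."""
    if len(stack) == 0:
        raise ValueError("cannot align an empty stack")
    names = stack.names
    ref = stack[names[0]].geometry
    for name in names[1:]:
        if not ref.matches(stack[name].geometry):
            raise AlignmentError(f"layer {name!r} deviates from the shared geometry")
    return ref


def cell_of(
    point: tuple[float, float], geom: GridGeometry
) -> tuple[int, int] | None:
    """Map a projected point to its (row, col) cell, or None if outside.

    Half-open convention: a point on a cell's north or west edge belongs to
    that cell, so the east and south outer edges of the extent are outside.
    """
    x, y = point
    x0, y0 = geom.origin_xy
    cs = geom.cell_size_km
    col = math.floor((x - x0) / cs)
    row = math.floor((y0 - y) / cs)
    if 0 <= row < geom.n_rows and 0 <= col < geom.n_cols:
        return (row, col)
    return None


def cell_center(row: int, col: int, geom: GridGeometry) -> tuple[float, float]:
    """Projected (x, y) of a cell center."""
    x0, y0 = geom.origin_xy
    cs = geom.cell_size_km
    return (x0 + (col + 0.5) * cs, y0 - (row + 0.5) * cs)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_ASC_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
_UNIT_TO_KM = {"km": 1.0, "m": 0.001}


def read_grid(
    path: str | Path,
    format: str = "ascii_grid",
    unit: str = "km",
    layer_name: str | None = None,
) -> Grid:
    """Read a single-band raster.

    Only the ESRI ASCII grid dialect is supported; ``format="geotiff"``
    raises an unsupported-input error. ``unit`` names the linear unit of the
    file's cellsize/corner coordinates (``"km"`` or ``"m"``); values are
    converted so the returned Grid is always in km.
    """
    path = Path(path)
    if format == "geotiff":
        raise GridFormatError("geotiff input is not supported; provide ascii_grid")
    if format != "ascii_grid":
        raise GridFormatError(f"unknown raster format {format!r}")
    if unit not in _UNIT_TO_KM:
        raise ValueError(f"unit must be one of {sorted(_UNIT_TO_KM)}")
    scale = _UNIT_TO_KM[unit]

    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    # header: leading keyword/value lines, keywords case-insensitive
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _ASC_KEYS:
            key = parts[0].lower()
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"malformed header value for {key!r}") from exc
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise GridFormatError(f"missing required header key {req!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if ncols <= 0 or nrows <= 0 or ncols != header["ncols"] or nrows != header["nrows"]:
        raise GridFormatError("ncols/nrows must be positive integers")
    nodata = header.get("nodata_value", -9999.0)

    body = " ".join(lines[i:]).split()
    if len(body) != nrows * ncols:
        raise GridFormatError(
            f"expected {nrows * ncols} cell values, found {len(body)}"
        )
    try:
        values = np.array(body, dtype=float).reshape(nrows, ncols)
    except ValueError as exc:
        raise GridFormatError("non-numeric cell value in grid body") from exc

    mask = values == nodata
    cell_size_km = header["cellsize"] * scale
    origin_xy = (
        header["xllcorner"] * scale,
        header["yllcorner"] * scale + nrows * cell_size_km,
    )
    values = values.copy()
    values[mask] = np.nan
    return Grid(
        values=values,
        nodata_mask=mask,
        cell_size_km=cell_size_km,
        origin_xy=origin_xy,
        layer_name=layer_name if layer_name is not None else path.stem,
    )


def write_grid(grid: Grid, path: str | Path, nodata: float = -9999.0) -> None:
    """Write a Grid as an ESRI ASCII grid (km units, repr-precision floats)."""
    path = Path(path)
    nrows, ncols = grid.values.shape
    xll = grid.origin_xy[0]
    yll = grid.origin_xy[1] - nrows * grid.cell_size_km
    out = grid.values.copy()
    out[grid.nodata_mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(xll)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size_km)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for r in range(nrows):
            fh.write(" ".join(repr(float(v)) for v in out[r]) + "\n")


def read_points_csv(path: str | Path) -> np.ndarray:
    """Read an (n, 2) array of x,y points from a CSV with header x,y."""
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise GridFormatError("point CSV must have columns 'x' and 'y'")
    return df[["x", "y"]].to_numpy(dtype=float)


def write_points_csv(points: np.ndarray, path: str | Path) -> None:
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    pd.DataFrame(pts, columns=["x", "y"]).to_csv(path, index=False)
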