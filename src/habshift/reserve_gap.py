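"""Protected-area gap analysis: overlay habitat with reserve boundaries.

Reserves arrive as GeoJSON polygons (or an already-rasterized label grid).
A cell belongs to a reserve iff its center lies inside the polygon —
membership by cell center keeps every reported area an exact multiple of
the cell area. Overlapping polygons are resolved first-listed-wins for
labeling, but the network protection percentages use the union of all
reserves, so overlaps are never double counted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .grid_model import AlignmentError, Grid, GridGeometry, cell_center
from .habitat_change import BinaryHabitatMap

__all__ = [
    "ReserveSet",
    "ReserveReport",
    "load_reserves_geojson",
    "rasterize_reserves",
    "per_reserve_areas",
    "reserve_change",
    "network_protection",
    "build_reserve_report",
]

logger = logging.getLogger(__name__)


@dataclass
class ReserveSet:
    """Named reserve polygons; names unique, geometries valid."""

    names: list[str]
    geometries: list  # shapely geometries, same order

    def __post_init__(self) -> None:
        if len(self.names) != len(self.geometries):
            raise ValueError("names and geometries differ in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("reserve names must be unique")
        for name, geom in zip(self.names, self.geometries):
            if not geom.is_valid:
                raise ValueError(f"reserve {name!r} has an invalid geometry")

    def __len__(self) -> int:
        return len(self.names)


def load_reserves_geojson(source: str | Path | dict) -> ReserveSet:
    """Read a GeoJSON FeatureCollection of reserve polygons.

    Features are named from a ``name`` property (falling back to a running
    index).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = json.load(fh)
    else:
        data = source
    if data.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    names, geoms = [], []
    for i, feat in enumerate(data.get("features", [])):
        props = feat.get("properties") or {}
        names.append(str(props.get("name", f"reserve_{i + 1}")))
        geoms.append(shapely_shape(feat["geometry"]))
    return ReserveSet(names=names, geometries=geoms)


def rasterize_reserves(reserves: ReserveSet, geom: GridGeometry) -> np.ndarray:
    """Label grid: cell → 1-based reserve index, 0 = unprotected.

    A cell is assigned to the first listed reserve whose polygon contains
    the cell center; overlaps are logged.
    """
    labels = np.zeros(geom.shape, dtype=np.int32)
    rows, cols = np.meshgrid(np.arange(geom.n_rows), np.arange(geom.n_cols), indexing="ij")
    xs = geom.origin_xy[0] + (cols + 0.5) * geom.cell_size_km
    ys = geom.origin_xy[1] - (rows + 0.5) * geom.cell_size_km
    overlap_cells = 0
    for i, (name, poly) in enumerate(zip(reserves.names, reserves.geometries), start=1):
        inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel()).reshape(geom.shape)
        if not inside.any():
            logger.warning("reserve %r labels no cell (outside the extent?)", name)
        already = inside & (labels > 0)
        if already.any():
            overlap_cells += int(already.sum())
        labels[inside & (labels == 0)] = i
    if overlap_cells:
        logger.warning(
            "%d cell(s) fall in more than one reserve; first-listed wins", overlap_cells
        )
    return labels


def per_reserve_areas(
    labels: np.ndarray,
    habitat: BinaryHabitatMap,
    reserve_names: list[str],
) -> pd.Series:
    """Suitable area (km²) inside each reserve; zero-overlap reserves → 0.0."""
    if labels.shape != habitat.suitable.shape:
        raise AlignmentError("reserve label grid does not align with the habitat map")
    cell_area = habitat.grid.cell_size_km**2
    counts = np.bincount(
        labels[habitat.suitable].ravel(), minlength=len(reserve_names) + 1
    )
    areas = counts[1 : len(reserve_names) + 1] * cell_area
    return pd.Series(areas, index=list(reserve_names), name="suitable_km2")


def reserve_change(areas_current: pd.Series, areas_future: pd.Series) -> pd.DataFrame:
    """Per-reserve percentage of area change.

    AC = (future − current) / current × 100; reserves with zero current
    suitable area get NaN (rendered as "—" downstream).
    """
    if set(areas_current.index) != set(areas_future.index):
        raise ValueError("current and future area tables name different reserves")
    fut = areas_future.reindex(areas_current.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ac = (fut - areas_current) / areas_current * 100.0
    ac = ac.where(areas_current > 0, np.nan)
    return pd.DataFrame(
        {
            "current_km2": areas_current,
            "future_km2": fut,
            "ac_pct": ac,
        }
    )


def network_protection(
    labels: np.ndarray,
    habitat_current: BinaryHabitatMap,
    habitat_future: BinaryHabitatMap,
) -> tuple[float, float]:
    """Percentage of suitable area inside any reserve, per scenario."""
    protected = labels > 0
    out = []
    for hab in (habitat_current, habitat_future):
        if labels.shape != hab.suitable.shape:
            raise AlignmentError("reserve label grid does not align with the habitat map")
        total = int(np.count_nonzero(hab.suitable))
        if total == 0:
            raise ValueError("habitat map is empty; protection percentage undefined")
        out.append(100.0 * np.count_nonzero(hab.suitable & protected) / total)
    return out[0], out[1]


@dataclass
class ReserveReport:
    table: pd.DataFrame  # per reserve: current_km2, future_km2, ac_pct
    protected_current_pct: float
    protected_future_pct: float


def build_reserve_report(
    reserves: ReserveSet,
    habitat_current: BinaryHabitatMap,
    habitat_future: BinaryHabitatMap,
) -> ReserveReport:
    """Rasterize, overlay, and summarize in one step."""
    labels = rasterize_reserves(reserves, habitat_current.grid.geometry)
    cur = per_reserve_areas(labels, habitat_current, reserves.names)
    fut = per_reserve_areas(labels, habitat_future, reserves.names)
    table = reserve_change(cur, fut)
    p_cur, p_fut = network_protection(labels, habitat_current, habitat_future)
    return ReserveReport(
        table=table, protected_current_pct=p_cur, protected_future_pct=p_fut
    )
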