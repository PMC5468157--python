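"""Published study values used as inputs to the arithmetic checks.

The printed per-reserve suitable-area table and the printed scenario areas
(current 4,810 km², 2050s 4,529 km², overlap 3,823 km²) for the Qinling
giant-panda assessment are shipped as package data. They are *inputs*: the
package's indicator and overlay operations are run on them to verify that
the arithmetic reproduces the published percentages.

:func:`table1_raster_fixture` rebuilds the table as an actual raster
overlay problem — a synthetic label grid plus current/future habitat maps
at 0.1 km resolution whose per-reserve suitable areas equal the printed
columns (printed areas have two decimals, i.e. are exact multiples of the
0.01 km² cell area) — so the gap-analysis code path itself, not just the
division, is exercised.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .grid_model import Grid
from .habitat_change import BinaryHabitatMap

__all__ = ["load_reserve_table", "scenario_areas", "table1_raster_fixture"]

_CELL_KM = 0.1  # printed areas are exact multiples of 0.01 km²


def load_reserve_table() -> pd.DataFrame:
    """Printed per-reserve table: current_km2, future_km2, ac_pct (NaN = —)."""
    with resources.files("habshift.data").joinpath("reserve_table.csv").open() as fh:
        return pd.read_csv(fh, index_col="reserve")


def scenario_areas() -> dict[str, float]:
    """Printed scenario areas A_c, A_f, A_fc in km²."""
    with resources.files("habshift.data").joinpath("scenario_areas.json").open() as fh:
        return json.load(fh)


def table1_raster_fixture() -> tuple[np.ndarray, BinaryHabitatMap, BinaryHabitatMap, list[str]]:
    """Synthetic raster overlay whose areas equal the printed table.

    Returns (labels, habitat_current, habitat_future, reserve_names). Cells
    are laid out in row-major blocks, one block per reserve (label 1..19)
    sized to the larger of its two printed areas, followed by an unprotected
    block carrying the rest of the printed scenario totals; within a block
    the first cells are suitable. The geometry is synthetic — only the areas
    are faithful to the publication.
    """
    table = load_reserve_table()
    areas = scenario_areas()
    cell_area = _CELL_KM**2

    blocks: list[tuple[int, int, int]] = []  # (label, n_cur, n_fut)
    for label, (_, row) in enumerate(table.iterrows(), start=1):
        n_cur = round(row["current_km2"] / cell_area)
        n_fut = round(row["future_km2"] / cell_area)
        blocks.append((label, n_cur, n_fut))
    out_cur = round(areas["area_current_km2"] / cell_area) - sum(b[1] for b in blocks)
    out_fut = round(areas["area_future_km2"] / cell_area) - sum(b[2] for b in blocks)
    blocks.append((0, out_cur, out_fut))

    n_cells = sum(max(nc, nf) for _, nc, nf in blocks)
    n_cols = 1000
    n_rows = -(-n_cells // n_cols)

    labels = np.zeros(n_rows * n_cols, dtype=np.int32)
    cur = np.zeros(n_rows * n_cols, dtype=bool)
    fut = np.zeros(n_rows * n_cols, dtype=bool)
    pos = 0
    for label, n_cur, n_fut in blocks:
        width = max(n_cur, n_fut)
        labels[pos : pos + width] = label
        cur[pos : pos + n_cur] = True
        fut[pos : pos + n_fut] = True
        pos += width

    shape = (n_rows, n_cols)
    carrier = Grid(
        values=np.zeros(shape),
        nodata_mask=np.zeros(shape, dtype=bool),
        cell_size_km=_CELL_KM,
        origin_xy=(0.0, n_rows * _CELL_KM),
        layer_name="table1_fixture",
    )
    hab_cur = BinaryHabitatMap(
        suitable=cur.reshape(shape), grid=carrier, threshold_used=0.5, scenario_label="current"
    )
    hab_fut = BinaryHabitatMap(
        suitable=fut.reshape(shape), grid=carrier, threshold_used=0.5, scenario_label="future"
    )
    return labels.reshape(shape), hab_cur, hab_fut, list(table.index)
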