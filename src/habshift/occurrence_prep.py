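"""Presence thinning and target-group background generation.

Presence records are thinned to one per grid cell (chosen uniformly at
random among a cell's records) so that repeatedly-surveyed cells do not
dominate the likelihood. Background points are drawn uniformly from forest
cells — a target-group background: because sign surveys happen in forest,
contrasting presences against forest rather than the whole landscape cancels
that survey bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid_model import Grid, GridGeometry, cell_of

__all__ = ["OccurrenceSet", "BackgroundSet", "thin_one_per_cell", "sample_background"]

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presence points in projected km with a provenance note."""

    points: np.ndarray  # (n, 2) x, y
    provenance: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class BackgroundSet:
    points: np.ndarray
    n_requested: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.points.shape[0]


def thin_one_per_cell(
    occ: OccurrenceSet, geom: GridGeometry, seed: int = 0
) -> OccurrenceSet:
    """Keep exactly one record per occupied cell, uniformly at random.

    Points outside the grid extent are dropped (count logged). Output rows
    are ordered by (row, col) of the retained cell, so the result is stable
    across input orderings up to the within-cell choice.
    """
    if len(occ) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    cells: dict[tuple[int, int], list[int]] = {}
    n_outside = 0
    for i, (x, y) in enumerate(occ.points):
        rc = cell_of((x, y), geom)
        if rc is None:
            n_outside += 1
            continue
        cells.setdefault(rc, []).append(i)
    if n_outside:
        logger.info("thinning dropped %d point(s) outside the grid extent", n_outside)
    if not cells:
        raise ValueError("all occurrence points fall outside the grid extent")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for rc in sorted(cells):
        members = cells[rc]
        keep.append(members[int(rng.integers(len(members)))])
    return OccurrenceSet(
        points=occ.points[keep],
        provenance=f"{occ.provenance} | thinned one-per-cell "
        f"({len(occ)}→{len(keep)}, {n_outside} outside)",
    )


def sample_background(
    forest: Grid,
    n: int = 10_000,
    seed: int = 0,
    exclude: OccurrenceSet | None = None,
) -> BackgroundSet:
    """Draw n target-group background points uniformly over forest cells.

    Cells are chosen uniformly with replacement, positions jittered within
    the cell. ``exclude`` removes the cells occupied by the given presence
    set from the candidate pool (off by default: standard presence-background
    practice lets background fall on presence cells).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    geom = forest.geometry
    eligible = forest.valid_mask & (forest.values > 0)
    if exclude is not None:
        for x, y in exclude.points:
            rc = cell_of((x, y), geom)
            if rc is not None:
                eligible[rc] = False
    flat_idx = np.flatnonzero(eligible.ravel())
    if flat_idx.size == 0:
        raise ValueError("no eligible forest cell to sample background from")
    rng = np.random.default_rng(seed)
    chosen = flat_idx[rng.integers(flat_idx.size, size=n)]
    rows, cols = np.unravel_index(chosen, geom.shape)
    jitter = rng.uniform(0.0, 1.0, size=(n, 2))
    cs = geom.cell_size_km
    x0, y0 = geom.origin_xy
    xs = x0 + (cols + jitter[:, 0]) * cs
    ys = y0 - (rows + jitter[:, 1]) * cs
    return BackgroundSet(points=np.column_stack([xs, ys]), n_requested=n)
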