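"""Binary habitat mapping, patch filtering, and range-shift vulnerability.

Continuous suitability is cut at a threshold (inclusive: a cell exactly at
the threshold is suitable) into a binary habitat map. Connected suitable
patches are then filtered by a home-range/dispersal rule: a patch is removed
only if it is both smaller than the minimum home range (default 4 km²) AND
farther than the mean daily dispersal distance (default 0.5 km edge-to-edge
gap) from every other retained patch; removal is iterated to a fixed point
because removing one patch can isolate another.

Comparing the current and future habitat maps cell by cell yields four
categories — unchanged, vulnerable (suitable now, not in the future), new
(the reverse), and unsuitable — and three indicators over the areas
A_c (current suitable), A_f (future suitable), A_fc (overlap):

    AC   = (A_f − A_c) / A_c × 100      percentage area change
    SH_c = (A_c − A_fc) / A_c × 100     % of current habitat lost
    SH_f = (A_f − A_fc) / A_f × 100     % of future habitat newly gained

A Mann–Whitney rank test contrasts the elevations of suitable cells under
the two scenarios (upslope shifts being the expected climate signature).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm, rankdata

from .grid_model import AlignmentError, Grid

__all__ = [
    "BinaryHabitatMap",
    "PatchSet",
    "ChangeMap",
    "VulnerabilityIndicators",
    "RankTestResult",
    "binarize",
    "label_patches",
    "filter_patches",
    "classify_change",
    "indicators",
    "indicators_from_areas",
    "mann_whitney",
    "elevation_contrast",
]

# change-category codes (also the coded .asc convention)
UNSUITABLE, UNCHANGED, VULNERABLE, NEW = 0, 1, 2, 3


@dataclass
class BinaryHabitatMap:
    """Thresholded suitability; suitable implies valid."""

    suitable: np.ndarray  # bool
    grid: Grid  # geometry + validity carrier
    threshold_used: float
    scenario_label: str = ""

    def __post_init__(self) -> None:
        self.suitable = np.asarray(self.suitable, dtype=bool)
        if self.suitable.shape != self.grid.values.shape:
            raise ValueError("suitable mask shape differs from grid shape")
        # suitable ⇒ valid
        self.suitable &= self.grid.valid_mask

    @property
    def area_km2(self) -> float:
        return float(np.count_nonzero(self.suitable)) * self.grid.cell_size_km**2


@dataclass
class PatchRecord:
    patch_id: int
    n_cells: int
    area_km2: float
    bbox: tuple[int, int, int, int]  # row0, col0, row1, col1 inclusive


@dataclass
class PatchSet:
    labels: np.ndarray  # int, 0 = no patch
    patches: list[PatchRecord]
    cell_size_km: float
    source: BinaryHabitatMap


def binarize(suitability: Grid, threshold: float, scenario_label: str = "") -> BinaryHabitatMap:
    """Suitable ⇔ value >= threshold, on valid cells only."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    with np.errstate(invalid="ignore"):
        suitable = (suitability.values >= threshold) & suitability.valid_mask
    return BinaryHabitatMap(
        suitable=suitable,
        grid=suitability,
        threshold_used=float(threshold),
        scenario_label=scenario_label,
    )


_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


def label_patches(habitat: BinaryHabitatMap, connectivity: int = 8) -> PatchSet:
    """Connected-component patches under 4- or 8-neighbour adjacency."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(habitat.suitable, structure=_STRUCTURES[connectivity])
    cell_area = habitat.grid.cell_size_km**2
    patches: list[PatchRecord] = []
    if n:
        objects = ndimage.find_objects(labels)
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        for pid in range(1, n + 1):
            sl = objects[pid - 1]
            patches.append(
                PatchRecord(
                    patch_id=pid,
                    n_cells=int(counts[pid]),
                    area_km2=float(counts[pid]) * cell_area,
                    bbox=(sl[0].start, sl[1].start, sl[0].stop - 1, sl[1].stop - 1),
                )
            )
    return PatchSet(labels=labels, patches=patches, cell_size_km=habitat.grid.cell_size_km, source=habitat)


def _pairwise_patch_gaps(patches: PatchSet) -> np.ndarray:
    """Min edge-to-edge gap (km) between every patch pair.

    Gap = closest cell-center distance minus one cell size, floored at 0, so
    orthogonally or diagonally adjacent cells have gap 0 (diagonal centers
    are √2 cells apart, √2 − 1 < 0.5 cell) — adjacency never reads as
    isolation.
    """
    cs = patches.cell_size_km
    n = len(patches.patches)
    gaps = np.full((n, n), np.inf)
    cells = []
    for rec in patches.patches:
        rr, cc = np.nonzero(patches.labels == rec.patch_id)
        cells.append(np.column_stack([(cc + 0.5) * cs, (rr + 0.5) * cs]))
    trees = [cKDTree(c) for c in cells]
    for i in range(n):
        for j in range(i + 1, n):
            d, _ = trees[j].query(cells[i], k=1)
            center_min = float(d.min())
            gaps[i, j] = gaps[j, i] = max(center_min - cs, 0.0)
    return gaps


def filter_patches(
    patches: PatchSet,
    min_area_km2: float = 4.0,
    max_gap_km: float = 0.5,
) -> BinaryHabitatMap:
    """Remove patches that are both small and isolated, to a fixed point.

    A patch is removed iff area < min_area_km2 AND its minimum gap to the
    nearest *other retained* patch exceeds max_gap_km (a lone patch has
    infinite gap). Removal rounds repeat until stable, since removing a
    patch can isolate a neighbour.
    """
    n = len(patches.patches)
    src = patches.source
    if n == 0:
        return BinaryHabitatMap(
            suitable=np.zeros_like(src.suitable),
            grid=src.grid,
            threshold_used=src.threshold_used,
            scenario_label=src.scenario_label,
        )
    gaps = _pairwise_patch_gaps(patches)
    areas = np.array([rec.area_km2 for rec in patches.patches])
    small = areas < min_area_km2
    retained = np.ones(n, dtype=bool)
    while True:
        remove = np.zeros(n, dtype=bool)
        for i in np.flatnonzero(retained & small):
            others = retained.copy()
            others[i] = False
            min_gap = gaps[i, others].min() if others.any() else np.inf
            if min_gap > max_gap_km:
                remove[i] = True
        if not remove.any():
            break
        retained &= ~remove
    keep_ids = {patches.patches[i].patch_id for i in np.flatnonzero(retained)}
    suitable = np.isin(patches.labels, sorted(keep_ids))
    return BinaryHabitatMap(
        suitable=suitable,
        grid=src.grid,
        threshold_used=src.threshold_used,
        scenario_label=src.scenario_label,
    )


@dataclass
class ChangeMap:
    """Four-category habitat transition map.

    Codes: 0 unsuitable, 1 unchanged, 2 vulnerable, 3 new; valid domain =
    cells valid in both scenarios. The categories partition the valid
    domain.
    """

    categories: np.ndarray  # int codes
    valid: np.ndarray  # bool
    cell_size_km: float
    current_label: str = "current"
    future_label: str = "future"

    def area_of(self, code: int) -> float:
        return float(np.count_nonzero((self.categories == code) & self.valid)) * self.cell_size_km**2


def classify_change(current: BinaryHabitatMap, future: BinaryHabitatMap) -> ChangeMap:
    """Cellwise: (S,S)→unchanged, (S,U)→vulnerable, (U,S)→new, (U,U)→unsuitable."""
    if not current.grid.geometry.matches(future.grid.geometry):
        raise AlignmentError("current and future habitat maps are not aligned")
    valid = current.grid.valid_mask & future.grid.valid_mask
    cur = current.suitable & valid
    fut = future.suitable & valid
    cats = np.full(cur.shape, UNSUITABLE, dtype=np.int8)
    cats[cur & fut] = UNCHANGED
    cats[cur & ~fut] = VULNERABLE
    cats[~cur & fut] = NEW
    cats[~valid] = UNSUITABLE
    return ChangeMap(
        categories=cats,
        valid=valid,
        cell_size_km=current.grid.cell_size_km,
        current_label=current.scenario_label or "current",
        future_label=future.scenario_label or "future",
    )


@dataclass
class VulnerabilityIndicators:
    a_c_km2: float  # current suitable area
    a_f_km2: float  # future suitable area
    a_fc_km2: float  # overlapped (unchanged) suitable area
    ac_pct: float | None  # percentage area change; None when A_c = 0
    sh_c_pct: float | None  # % of current habitat lost; None when A_c = 0
    sh_f_pct: float | None  # % of future habitat newly gained; None when A_f = 0

    @property
    def vulnerable_km2(self) -> float:
        return self.a_c_km2 - self.a_fc_km2

    @property
    def new_km2(self) -> float:
        return self.a_f_km2 - self.a_fc_km2

    @property
    def net_change_km2(self) -> float:
        return self.a_f_km2 - self.a_c_km2


def indicators_from_areas(a_c: float, a_f: float, a_fc: float) -> VulnerabilityIndicators:
    """The three indicators straight from the areas (km²)."""
    if a_fc > min(a_c, a_f) + 1e-9:
        raise ValueError("overlap area cannot exceed either scenario's area")
    ac = (a_f - a_c) / a_c * 100.0 if a_c > 0 else None
    sh_c = (a_c - a_fc) / a_c * 100.0 if a_c > 0 else None
    sh_f = (a_f - a_fc) / a_f * 100.0 if a_f > 0 else None
    return VulnerabilityIndicators(
        a_c_km2=a_c, a_f_km2=a_f, a_fc_km2=a_fc, ac_pct=ac, sh_c_pct=sh_c, sh_f_pct=sh_f
    )


def indicators(change: ChangeMap) -> VulnerabilityIndicators:
    """Indicators measured on a change map: A_c = unchanged + vulnerable,
    A_f = unchanged + new, A_fc = unchanged."""
    a_fc = change.area_of(UNCHANGED)
    a_c = a_fc + change.area_of(VULNERABLE)
    a_f = a_fc + change.area_of(NEW)
    return indicators_from_areas(a_c, a_f, a_fc)


# ---------------------------------------------------------------------------
# Mann–Whitney elevation contrast
# ---------------------------------------------------------------------------

#: enumerate the exact permutation distribution when the number of
#: arrangements C(n1+n2, n1) is at most this
_EXACT_MAX_ARRANGEMENTS = 20_000


@dataclass
class RankTestResult:
    u: float
    z: float
    p: float
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    exact: bool  # p from exact enumeration rather than normal approximation


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def mann_whitney(group1: np.ndarray, group2: np.ndarray) -> RankTestResult:
    """Two-sided Mann–Whitney U test.

    The z statistic always comes from the tie-corrected normal approximation
    with a 0.5 continuity correction toward the mean. The p-value is exact
    (full enumeration of group assignments, tie-safe) whenever the number of
    arrangements C(n1+n2, n1) is small enough, otherwise from z.
    """
    x = np.asarray(group1, dtype=float).ravel()
    y = np.asarray(group2, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    combined = np.concatenate([x, y])
    nn = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (nn * (nn - 1.0))
    var = n1 * n2 / 12.0 * ((nn + 1.0) - tie_term)
    if var <= 0:
        z = 0.0
    else:
        diff = u - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
    p_norm = 2.0 * norm.sf(abs(z))

    exact = math.comb(nn, n1) <= _EXACT_MAX_ARRANGEMENTS
    if exact:
        obs_dev = abs(u - mu)
        count = 0
        total = 0
        for pos in itertools.combinations(range(nn), n1):
            mask = np.zeros(nn, dtype=bool)
            mask[list(pos)] = True
            u_perm = _u_statistic(combined[mask], combined[~mask])
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                count += 1
        p = count / total
    else:
        p = min(p_norm, 1.0)

    return RankTestResult(
        u=u,
        z=float(z),
        p=float(p),
        n1=n1,
        n2=n2,
        mean1=float(x.mean()),
        sd1=float(x.std(ddof=1)) if n1 > 1 else 0.0,
        mean2=float(y.mean()),
        sd2=float(y.std(ddof=1)) if n2 > 1 else 0.0,
        exact=exact,
    )


def elevation_contrast(
    current: BinaryHabitatMap, future: BinaryHabitatMap, elevation: Grid
) -> RankTestResult:
    """Rank test on elevations of suitable cells, current vs future.

    One value per suitable cell; group 1 = current scenario, group 2 =
    future. A positive future minus current mean with |z| large indicates an
    upslope shift.
    """
    cur_vals = elevation.values[current.suitable & elevation.valid_mask]
    fut_vals = elevation.values[future.suitable & elevation.valid_mask]
    if cur_vals.size == 0 or fut_vals.size == 0:
        raise ValueError("both scenarios must have non-empty suitable habitat")
    return mann_whitney(cur_vals, fut_vals)
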