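"""Correlation-based predictor screening and the importance refit rule.

Two screening stages precede the final model: (1) among the candidate
layers, one member of every strongly correlated pair (default |r| > 0.8,
Pearson, computed at the presence + background points) is eliminated; (2)
after a first model fit, only variables whose permutation importance reaches
a cutoff (default 1%) are kept for the final fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_model import GridStack, cell_of

__all__ = [
    "ScreenConfig",
    "ScreenReport",
    "pairwise_correlation",
    "eliminate_correlated",
    "refit_top_variables",
    "extract_at_points",
]


@dataclass(frozen=True)
class ScreenConfig:
    correlation_cutoff: float = 0.8
    importance_cutoff_pct: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.correlation_cutoff <= 1.0):
            raise ValueError("correlation_cutoff must lie in (0, 1]")
        if not np.isfinite(self.importance_cutoff_pct) or self.importance_cutoff_pct < 0:
            raise ValueError("importance_cutoff_pct must be finite and >= 0")


@dataclass
class ScreenReport:
    correlation: pd.DataFrame
    eliminated: list[tuple[str, str]]  # (dropped, partner that triggered it)
    retained: list[str]
    flagged_constant: list[str] = field(default_factory=list)


def extract_at_points(stack: GridStack, points: np.ndarray) -> pd.DataFrame:
    """Layer values at projected points; rows outside the extent or on any
    nodata cell are dropped."""
    geom = stack.geometry
    rows, cols = [], []
    for x, y in np.asarray(points, dtype=float).reshape(-1, 2):
        rc = cell_of((x, y), geom)
        if rc is not None:
            rows.append(rc[0])
            cols.append(rc[1])
    if not rows:
        return pd.DataFrame(columns=stack.names)
    df = stack.values_at_cells(np.array(rows), np.array(cols))
    return df.dropna(axis=0).reset_index(drop=True)


def pairwise_correlation(
    stack: GridStack, sample_points: np.ndarray
) -> pd.DataFrame:
    """Pearson correlation between layers at the sample points.

    Zero-variance layers get NaN against every other layer (flagged rather
    than eliminated by correlation); the diagonal is exactly 1.
    """
    df = extract_at_points(stack, sample_points)
    if len(df) < 3:
        raise ValueError("need at least 3 valid sample points for correlations")
    vals = df.to_numpy(dtype=float)
    names = list(df.columns)
    sd = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    corr[sd == 0.0, :] = np.nan
    corr[:, sd == 0.0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def eliminate_correlated(
    corr: pd.DataFrame,
    cfg: ScreenConfig = ScreenConfig(),
    priority: dict[str, float] | None = None,
) -> ScreenReport:
    """Greedy elimination until no retained pair exceeds the cutoff.

    Repeatedly takes the worst-offending retained pair and drops its
    lower-priority member; absent priorities, the member with the larger
    mean |r| against all other retained layers is dropped, ties broken by
    dropping the alphabetically later name. Deterministic.
    """
    names = list(corr.columns)
    mat = corr.to_numpy(dtype=float).copy()
    if not np.allclose(np.nan_to_num(mat), np.nan_to_num(mat.T), atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    flagged = [n for i, n in enumerate(names) if np.isnan(np.delete(mat[i], i)).all() and len(names) > 1]

    retained = list(names)
    eliminated: list[tuple[str, str]] = []
    idx = {n: i for i, n in enumerate(names)}

    def offending_pair() -> tuple[str, str] | None:
        worst = None
        worst_r = cfg.correlation_cutoff
        for a_pos in range(len(retained)):
            for b_pos in range(a_pos + 1, len(retained)):
                a, b = retained[a_pos], retained[b_pos]
                r = abs(mat[idx[a], idx[b]])
                if np.isnan(r):
                    continue
                if r > worst_r:
                    worst_r = r
                    worst = (a, b)
        return worst

    def mean_abs_r(name: str) -> float:
        others = [idx[o] for o in retained if o != name]
        if not others:
            return 0.0
        vals = np.abs(mat[idx[name], others])
        vals = vals[~np.isnan(vals)]
        return float(vals.mean()) if vals.size else 0.0

    while True:
        pair = offending_pair()
        if pair is None:
            break
        a, b = pair
        if priority is not None:
            pa, pb = priority.get(a, -np.inf), priority.get(b, -np.inf)
            drop, keep = (a, b) if pa < pb else (b, a) if pb < pa else (max(a, b), min(a, b))
        else:
            ma, mb = mean_abs_r(a), mean_abs_r(b)
            drop, keep = (a, b) if ma > mb else (b, a) if mb > ma else (max(a, b), min(a, b))
        retained.remove(drop)
        eliminated.append((drop, keep))

    return ScreenReport(
        correlation=corr,
        eliminated=eliminated,
        retained=retained,
        flagged_constant=flagged,
    )


def refit_top_variables(
    first_model_importance: dict[str, float],
    cfg: ScreenConfig = ScreenConfig(),
) -> list[str]:
    """Variables whose permutation importance (%) reaches the cutoff.

    Inclusion is >= the cutoff; raises if nothing survives.
    """
    total = sum(first_model_importance.values())
    if first_model_importance and not np.isclose(total, 100.0, atol=1.0):
        raise ValueError(f"importances must sum to ~100, got {total:.3f}")
    retained = [
        name
        for name, imp in first_model_importance.items()
        if imp >= cfg.importance_cutoff_pct
    ]
    if not retained:
        raise ValueError(
            "importance cutoff removed every variable; lower importance_cutoff_pct"
        )
    return retained
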