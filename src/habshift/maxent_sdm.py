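"""Presence-background maximum-entropy species distribution model.

The model finds the probability distribution q_λ over a background sample
that is closest to uniform (maximum entropy) while matching the presence
sample's feature means, by maximizing the L1-penalized log-likelihood

    J(λ) = mean_presence[ λ·f(x) ] − log Z_λ − Σ_j β_j |λ_j|,
    q_λ(x) = exp(λ·f(x)) / Z_λ,   Z_λ = Σ_background exp(λ·f(x)).

Feature classes are linear, quadratic, and forward/reverse hinge (knots at
background quantiles), each scaled to [0, 1] over the background sample.
The optimizer is deterministic cyclic coordinate ascent with
soft-thresholding; because every feature lies in [0, 1], the per-coordinate
curvature of log Z is bounded by 1/4, so the fixed quadratic majorizer
h = 1/4 guarantees monotone convergence without line searches.

The logistic output p = e^H q / (1 + e^H q), with H the entropy of the
fitted distribution over the background, rescales raw densities to [0, 1];
a cell of "typical" suitability (q = e^{-H}) maps to 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grid_model import Grid, GridStack

__all__ = [
    "FeatureExpansion",
    "MaxentModel",
    "EvaluationResult",
    "ReplicateEnsemble",
    "build_features",
    "fit",
    "predict_scores",
    "predict_raw",
    "predict_logistic",
    "auc",
    "threshold_max_sss",
    "run_replicates",
    "permutation_importance",
    "jackknife_gain",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature expansion
# ---------------------------------------------------------------------------


@dataclass
class FeatureExpansion:
    """Per-variable feature definitions with background scaling bounds.

    Feature order is fixed: for each variable (input order) — linear,
    quadratic, forward hinges (knots ascending), reverse hinges (knots
    ascending). Raw values are clamped to the background [min, max] before
    evaluation, so every feature maps into [0, 1].
    """

    variables: list[str]
    bounds: dict[str, tuple[float, float]]
    fwd_knots: dict[str, np.ndarray]
    rev_knots: dict[str, np.ndarray]
    degenerate: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        names: list[str] = []
        for v in self.variables:
            names.append(f"{v}:linear")
            names.append(f"{v}:quadratic")
            names += [f"{v}:hinge_fwd@{k:g}" for k in self.fwd_knots[v]]
            names += [f"{v}:hinge_rev@{k:g}" for k in self.rev_knots[v]]
        return names

    def feature_variable(self) -> list[str]:
        """Owning variable of each feature column."""
        owners: list[str] = []
        for v in self.variables:
            n = 2 + len(self.fwd_knots[v]) + len(self.rev_knots[v])
            owners += [v] * n
        return owners

    @property
    def n_features(self) -> int:
        return len(self.feature_variable())

    def transform(self, raw: pd.DataFrame) -> np.ndarray:
        """Raw variable values (one column per variable) → feature matrix."""
        cols: list[np.ndarray] = []
        for v in self.variables:
            x = raw[v].to_numpy(dtype=float)
            lo, hi = self.bounds[v]
            if hi <= lo:  # constant on background: degenerate zero feature
                z = np.zeros_like(x)
                cols.append(z)
                cols.append(z)
                continue
            xc = np.clip(x, lo, hi)
            z = (xc - lo) / (hi - lo)
            cols.append(z)
            cols.append(z**2)
            for k in self.fwd_knots[v]:
                cols.append(np.where(xc > k, (xc - k) / (hi - k), 0.0))
            for k in self.rev_knots[v]:
                cols.append(np.where(xc < k, (k - xc) / (k - lo), 0.0))
        return np.column_stack(cols) if cols else np.empty((len(raw), 0))


def build_features(background: pd.DataFrame, hinge_knots: int = 4) -> FeatureExpansion:
    """Define the feature expansion from the background sample.

    ``hinge_knots`` is the number K of interior knots per direction, placed
    at background quantiles i/(K+1); knots colliding with the bounds or each
    other are dropped. A variable constant over the background contributes a
    single degenerate (all-zero) feature pair and is flagged.
    """
    variables = list(background.columns)
    bounds: dict[str, tuple[float, float]] = {}
    fwd: dict[str, np.ndarray] = {}
    rev: dict[str, np.ndarray] = {}
    degenerate: list[str] = []
    for v in variables:
        x = background[v].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            logger.warning("variable %r is constant over the background", v)
            degenerate.append(v)
            bounds[v] = (float(x.min()), float(x.max()))
            fwd[v] = np.empty(0)
            rev[v] = np.empty(0)
            continue
        lo, hi = float(x.min()), float(x.max())
        bounds[v] = (lo, hi)
        if hinge_knots > 0:
            qs = np.quantile(x, np.arange(1, hinge_knots + 1) / (hinge_knots + 1))
            qs = np.unique(qs)
            qs = qs[(qs > lo) & (qs < hi)]
        else:
            qs = np.empty(0)
        fwd[v] = qs.copy()
        rev[v] = qs.copy()
    return FeatureExpansion(
        variables=variables, bounds=bounds, fwd_knots=fwd, rev_knots=rev, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model over a background sample."""

    weights: np.ndarray  # λ, one per feature
    log_partition: float  # log Z over the background sample
    entropy: float  # H of q_λ over the background
    regularization: np.ndarray  # per-feature β
    feature_expansion: FeatureExpansion | None
    n_presence: int
    n_background: int
    objective: float
    converged: bool
    n_iter: int

    @property
    def nonzero_features(self) -> int:
        return int(np.count_nonzero(self.weights))


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def fit(
    presences: np.ndarray,
    background: np.ndarray,
    beta_multiplier: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-7,
    expansion: FeatureExpansion | None = None,
) -> MaxentModel:
    """Fit λ by cyclic coordinate ascent on the penalized log-likelihood.

    ``presences`` and ``background`` are feature matrices (rows = points,
    columns = features in the expansion's fixed order). Default per-feature
    penalty β_j = beta_multiplier × s_j / √n_presence with s_j the feature's
    background standard deviation. Deterministic: fixed cyclic feature
    order, no stochastic initialization. With zero features the unconstrained
    maximum-entropy solution — the uniform distribution over the background,
    H = log m — is returned.
    """
    F_p = np.asarray(presences, dtype=float)
    F_b = np.asarray(background, dtype=float)
    if F_p.ndim != 2 or F_b.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if np.isnan(F_p).any() or np.isnan(F_b).any():
        raise ValueError("NaN in feature matrix")
    n, J = F_p.shape
    m = F_b.shape[0]
    if n < 2:
        raise ValueError("need at least 2 presence points")
    if F_b.shape[1] != J:
        raise ValueError("presence/background feature counts differ")

    if J == 0:
        return MaxentModel(
            weights=np.empty(0),
            log_partition=float(np.log(m)),
            entropy=float(np.log(m)),
            regularization=np.empty(0),
            feature_expansion=expansion,
            n_presence=n,
            n_background=m,
            objective=-float(np.log(m)),
            converged=True,
            n_iter=0,
        )

    sd = F_b.std(axis=0)
    beta = beta_multiplier * sd / np.sqrt(n)
    beta = np.maximum(beta, 1e-9)
    active = np.flatnonzero(sd > 0)  # zero-variance features stay at λ=0

    pmean = F_p.mean(axis=0)
    lam = np.zeros(J)
    eta = np.zeros(m)
    q = np.full(m, 1.0 / m)

    def objective() -> float:
        return float(pmean @ lam - logsumexp(eta) - beta @ np.abs(lam))

    prev_obj = objective()
    converged = False
    it = 0
    H_STEP = 4.0  # 1/h with the global curvature bound h = 1/4
    for it in range(1, max_iter + 1):
        for j in active:
            col = F_b[:, j]
            g = pmean[j] - float(q @ col)
            z = lam[j] + H_STEP * g
            new = _soft(z, H_STEP * beta[j])
            d = new - lam[j]
            if d != 0.0:
                lam[j] = new
                eta += d * col
                w = np.exp(eta - eta.max())
                q = w / w.sum()
        obj = objective()
        if abs(obj - prev_obj) <= tol * max(1.0, abs(prev_obj)):
            converged = True
            prev_obj = obj
            break
        prev_obj = obj
    if not converged:
        grad = pmean - F_b.T @ q
        logger.warning(
            "maxent fit did not converge in %d cycles (max |grad| %.3g)",
            max_iter,
            float(np.abs(grad[active]).max()) if active.size else 0.0,
        )

    logZ = float(logsumexp(eta))
    with np.errstate(divide="ignore"):
        entropy = float(-(q * np.where(q > 0, np.log(q), 0.0)).sum())
    return MaxentModel(
        weights=lam,
        log_partition=logZ,
        entropy=entropy,
        regularization=beta,
        feature_expansion=expansion,
        n_presence=n,
        n_background=m,
        objective=prev_obj,
        converged=converged,
        n_iter=it,
    )


def penalized_objective(
    model_weights: np.ndarray,
    presences: np.ndarray,
    background: np.ndarray,
    beta: np.ndarray,
) -> float:
    """J(λ) for arbitrary weights — shared by tests and jackknife gains."""
    lam = np.asarray(model_weights, dtype=float)
    eta = background @ lam
    return float(
        presences.mean(axis=0) @ lam - logsumexp(eta) - beta @ np.abs(lam)
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_scores(model: MaxentModel, raw: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(raw q, logistic p) at points given as raw variable columns."""
    if model.feature_expansion is None:
        raise ValueError("model carries no feature expansion")
    F = model.feature_expansion.transform(raw)
    return _scores_from_features(model, F)


def _scores_from_features(model: MaxentModel, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if model.weights.size == 0:
        q = np.full(F.shape[0], np.exp(-model.log_partition))
    else:
        log_q = F @ model.weights - model.log_partition
        q = np.exp(log_q)
    eh_q = np.exp(model.entropy) * q
    p = eh_q / (1.0 + eh_q)
    return q, p


def _stack_raw_values(model: MaxentModel, stack: GridStack) -> tuple[pd.DataFrame, np.ndarray]:
    assert model.feature_expansion is not None
    for v in model.feature_expansion.variables:
        if v not in stack:
            raise ValueError(f"variable {v!r} missing from the stack")
    sub = stack.subset(model.feature_expansion.variables)
    valid = sub.valid_mask
    rows, cols = np.nonzero(valid)
    raw = sub.values_at_cells(rows, cols)
    return raw, valid


def predict_raw(model: MaxentModel, stack: GridStack) -> Grid:
    """Raw maxent output q over the stack; sums to 1 over the background
    sample, relative elsewhere. Nodata propagates from every model layer."""
    raw, valid = _stack_raw_values(model, stack)
    q, _ = predict_scores(model, raw)
    geom = stack.geometry
    out = np.full(geom.shape, np.nan)
    out[valid] = q
    return Grid(
        values=out,
        nodata_mask=~valid,
        cell_size_km=geom.cell_size_km,
        origin_xy=geom.origin_xy,
        layer_name="suitability_raw",
    )


def predict_logistic(model: MaxentModel, stack: GridStack) -> Grid:
    """Logistic suitability p ∈ [0, 1]; strictly increasing in q."""
    raw, valid = _stack_raw_values(model, stack)
    _, p = predict_scores(model, raw)
    geom = stack.geometry
    out = np.full(geom.shape, np.nan)
    out[valid] = p
    return Grid(
        values=out,
        nodata_mask=~valid,
        cell_size_km=geom.cell_size_km,
        origin_xy=geom.origin_xy,
        layer_name="suitability_logistic",
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-sum AUC: P(presence outscores background), ties counting ½."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


@dataclass
class EvaluationResult:
    auc_train: float
    auc_test: float
    threshold_sss: float
    sensitivity: float
    specificity: float


def threshold_max_sss(
    presence_scores: np.ndarray, background_scores: np.ndarray
) -> tuple[float, float, float]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the distinct observed scores; sensitivity counts
    presences with score >= t (the threshold itself is suitable), specificity
    counts background with score < t. Ties go to the smallest t, retaining
    more habitat. Returns (threshold, sensitivity, specificity).
    """
    p = np.sort(np.asarray(presence_scores, dtype=float).ravel())
    b = np.sort(np.asarray(background_scores, dtype=float).ravel())
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    cand = np.unique(np.concatenate([p, b]))
    sens = 1.0 - np.searchsorted(p, cand, side="left") / p.size
    spec = np.searchsorted(b, cand, side="left") / b.size
    total = sens + spec
    best = int(np.argmax(total))  # argmax takes the first (smallest t) on ties
    return float(cand[best]), float(sens[best]), float(spec[best])


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------


@dataclass
class ReplicateEnsemble:
    models: list[MaxentModel]
    evaluations: list[EvaluationResult]
    partitions: list[tuple[np.ndarray, np.ndarray]]  # (train idx, test idx)
    mean_suitability: Grid
    mean_threshold: float
    auc_train_mean: float
    auc_train_sd: float
    auc_test_mean: float
    auc_test_sd: float


def run_replicates(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    stack: GridStack,
    n_rep: int = 15,
    train_frac: float = 0.75,
    seed: int = 0,
    hinge_knots: int = 4,
    beta_multiplier: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-7,
) -> ReplicateEnsemble:
    """Subsample replication: n_rep independent train/test presence splits.

    Presences/background are raw variable values (one column per model
    variable). The background and the feature expansion are shared across
    replicates; each replicate refits on its 75% training presences,
    reporting train/test AUC and a max-SSS threshold from training presence
    vs background logistic scores. The ensemble prediction is the cellwise
    arithmetic mean of the replicate logistic grids, and the ensemble
    threshold the arithmetic mean of replicate thresholds.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie in (0, 1)")
    n = len(presences)
    if n < 4:
        raise ValueError("need at least 4 presences for a train/test split")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 2), n - 1)

    expansion = build_features(background, hinge_knots=hinge_knots)
    F_b = expansion.transform(background)
    F_p = expansion.transform(presences)

    rng = np.random.default_rng(seed)
    geom = stack.geometry
    mean_vals = np.zeros(geom.shape)
    valid_ref: np.ndarray | None = None

    models, evals, parts = [], [], []
    thresholds = []
    for _ in range(n_rep):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        model = fit(
            F_p[tr],
            F_b,
            beta_multiplier=beta_multiplier,
            max_iter=max_iter,
            tol=tol,
            expansion=expansion,
        )
        _, p_tr = _scores_from_features(model, F_p[tr])
        _, p_te = _scores_from_features(model, F_p[te])
        _, p_bg = _scores_from_features(model, F_b)
        t, sens, spec = threshold_max_sss(p_tr, p_bg)
        ev = EvaluationResult(
            auc_train=auc(p_tr, p_bg),
            auc_test=auc(p_te, p_bg),
            threshold_sss=t,
            sensitivity=sens,
            specificity=spec,
        )
        grid = predict_logistic(model, stack)
        if valid_ref is None:
            valid_ref = grid.valid_mask
        mean_vals[valid_ref] += grid.values[valid_ref]
        models.append(model)
        evals.append(ev)
        parts.append((tr, te))
        thresholds.append(t)

    assert valid_ref is not None
    mean_vals = np.where(valid_ref, mean_vals / n_rep, np.nan)
    mean_grid = Grid(
        values=mean_vals,
        nodata_mask=~valid_ref,
        cell_size_km=geom.cell_size_km,
        origin_xy=geom.origin_xy,
        layer_name="suitability_mean",
    )
    tr_aucs = np.array([e.auc_train for e in evals])
    te_aucs = np.array([e.auc_test for e in evals])
    return ReplicateEnsemble(
        models=models,
        evaluations=evals,
        partitions=parts,
        mean_suitability=mean_grid,
        mean_threshold=float(np.mean(thresholds)),
        auc_train_mean=float(tr_aucs.mean()),
        auc_train_sd=float(tr_aucs.std(ddof=1)) if n_rep > 1 else 0.0,
        auc_test_mean=float(te_aucs.mean()),
        auc_test_sd=float(te_aucs.std(ddof=1)) if n_rep > 1 else 0.0,
    )


def ensemble_mean_logistic(models: list[MaxentModel], stack: GridStack) -> Grid:
    """Cellwise arithmetic mean of the replicate logistic grids on a stack."""
    if not models:
        raise ValueError("need at least one model")
    acc: np.ndarray | None = None
    valid: np.ndarray | None = None
    ref: Grid | None = None
    for model in models:
        grid = predict_logistic(model, stack)
        if acc is None:
            acc = np.zeros_like(grid.values)
            valid = grid.valid_mask
            ref = grid
        acc[valid] += grid.values[valid]
    assert acc is not None and valid is not None and ref is not None
    vals = np.where(valid, acc / len(models), np.nan)
    return ref.with_values(vals, layer_name="suitability_mean")


# ---------------------------------------------------------------------------
# variable importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model: MaxentModel,
    presences: pd.DataFrame,
    background: pd.DataFrame,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance (%) per variable.

    Each variable's raw values are permuted jointly across the stacked
    presence + background points; importance is the resulting training-AUC
    drop, floored at zero and normalized to sum to 100. If no permutation
    drops the AUC (e.g. an all-zero-weight model), importance is spread
    uniformly.
    """
    if model.feature_expansion is None:
        raise ValueError("model carries no feature expansion")
    variables = model.feature_expansion.variables
    n = len(presences)
    combined = pd.concat([presences, background], ignore_index=True)

    _, p_pres = predict_scores(model, presences)
    _, p_bg = predict_scores(model, background)
    base_auc = auc(p_pres, p_bg)

    rng = np.random.default_rng(seed)
    drops = {}
    for v in variables:
        shuffled = combined.copy()
        shuffled[v] = rng.permutation(shuffled[v].to_numpy())
        _, p_all = predict_scores(model, shuffled)
        drops[v] = max(base_auc - auc(p_all[:n], p_all[n:]), 0.0)
    total = sum(drops.values())
    if total <= 0:
        return {v: 100.0 / len(variables) for v in variables}
    return {v: 100.0 * d / total for v, d in drops.items()}


def jackknife_gain(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    hinge_knots: int = 4,
    beta_multiplier: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-7,
) -> dict:
    """Training gain with each variable alone and with each left out.

    Gain = penalized mean presence log-likelihood minus the uniform-model
    baseline log(1/m); the uniform model attains gain 0, so the full-model
    gain is non-negative. One feature expansion (built on all variables) is
    shared, so per-feature penalties are identical across the nested fits.
    """
    if len(background.columns) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    expansion = build_features(background, hinge_knots=hinge_knots)
    F_b = expansion.transform(background)
    F_p = expansion.transform(presences)
    owners = np.array(expansion.feature_variable())
    m = F_b.shape[0]

    def gain_for(col_mask: np.ndarray) -> float:
        model = fit(
            F_p[:, col_mask],
            F_b[:, col_mask],
            beta_multiplier=beta_multiplier,
            max_iter=max_iter,
            tol=tol,
        )
        return model.objective + float(np.log(m))

    variables = expansion.variables
    result = {
        "full": gain_for(np.ones(len(owners), dtype=bool)),
        "only": {},
        "without": {},
    }
    for v in variables:
        result["only"][v] = gain_for(owners == v)
        result["without"][v] = gain_for(owners != v)
    return result
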