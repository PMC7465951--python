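"""Validation machinery and variable selection.

Cross-validation uses interleaved "venetian blinds" folds.  Model complexity
(number of latent variables) is chosen as the smallest LV count whose RMSECV
is within a small relative margin of the minimum — a parsimony rule
operationalising "lowest RMSECV, fewest factors".  Any preprocessing that
learns statistics is refitted inside each training fold, so no held-out
information leaks into the fold models.

Variable selection offers four standard chemometric methods: VIP scores,
forward interval PLS (iPLS), recursive reweighted PLS (rPLS), and the
selectivity ratio from target projection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigurationError, DegenerateDataError
from .io import SpectralBlock
from .multivariate import PLSModel, fit_pls1, fit_plsda, classify, \
    classification_metrics, predict
from .preprocess import PreprocessRecipe

logger = logging.getLogger("milknir")


# ---------------------------------------------------------------------------
# Cross-validation plans

@dataclass(frozen=True)
class CrossValPlan:
    """Venetian-blinds plan: interleaved folds of consecutive runs."""

    n_splits: int = 22
    thickness: int = 5
    scheme: str = "venetian"

    def __post_init__(self) -> None:
        if self.scheme != "venetian":
            raise ConfigurationError(f"unknown CV scheme {self.scheme!r}")
        if self.n_splits < 2:
            raise ConfigurationError("n_splits must be >= 2")
        if self.thickness < 1:
            raise ConfigurationError("thickness must be >= 1")


def venetian_blinds(n_samples: int, plan: CrossValPlan) -> np.ndarray:
    """Fold assignment: sample i -> floor(i / thickness) mod n_splits.

    When ``n_splits * thickness`` exceeds the sample count the plan cannot
    be realised literally; it is adapted to thickness 1 (fully interleaved
    folds) with a logged warning.
    """
    if n_samples < plan.n_splits:
        raise ConfigurationError(
            f"cannot make {plan.n_splits} folds from {n_samples} samples")
    thickness = plan.thickness
    if plan.n_splits * thickness > n_samples:
        logger.warning(
            "venetian plan %d splits x %d per blind infeasible for n=%d; "
            "adapted to thickness 1", plan.n_splits, thickness, n_samples)
        thickness = 1
    i = np.arange(n_samples)
    return (i // thickness) % plan.n_splits


# ---------------------------------------------------------------------------
# Cross-validation of PLS1 complexity

@dataclass
class CrossValResult:
    """Per-LV cross-validation error curves and the selected complexity."""

    rmsecv: np.ndarray             # (max_lv,)
    r2: np.ndarray                 # (max_lv,) squared Pearson of CV preds
    n_lv: int                      # chosen complexity (1-based)
    predictions: np.ndarray        # (n, max_lv) CV predictions
    folds: np.ndarray              # (n,) fold assignment
    epsilon: float

    @property
    def rmsecv_selected(self) -> float:
        return float(self.rmsecv[self.n_lv - 1])

    @property
    def r2_selected(self) -> float:
        return float(self.r2[self.n_lv - 1])


def _as_matrix(X) -> np.ndarray:
    return X.reflectance if isinstance(X, SpectralBlock) else np.asarray(X, float)


def choose_n_lv(rmsecv: np.ndarray, epsilon: float = 0.02) -> int:
    """Smallest LV count with RMSECV <= (1 + epsilon) * min RMSECV."""
    rmsecv = np.asarray(rmsecv, float)
    limit = (1.0 + epsilon) * np.nanmin(rmsecv)
    return int(np.flatnonzero(rmsecv <= limit)[0]) + 1


def cross_validate(X, y: np.ndarray, recipe: PreprocessRecipe | None,
                   max_lv: int, plan: CrossValPlan,
                   epsilon: float = 0.02,
                   autoscale: bool = False) -> CrossValResult:
    """Venetian-blinds cross-validation of a PLS1 calibration.

    ``X`` may be a :class:`SpectralBlock` (required when ``recipe`` is not
    None, so preprocessing statistics can be refitted per fold) or a plain
    matrix.  ``autoscale=True`` scales columns by the training-fold SDs
    inside each fold (used for fused blocks).
    """
    if max_lv < 1:
        raise ConfigurationError("max_lv must be >= 1")
    if recipe is not None and not isinstance(X, SpectralBlock):
        raise ConfigurationError("a recipe requires a SpectralBlock input")
    y = np.asarray(y, float).ravel()
    n = len(y)
    folds = venetian_blinds(n, plan)
    sizes = np.bincount(folds, minlength=plan.n_splits)
    if np.any(sizes < 1):
        raise ConfigurationError("empty cross-validation fold")
    if np.any(n - sizes < 2):
        raise ConfigurationError("training fold with fewer than 2 samples")

    # cap LV count by what every training fold can support
    max_lv_eff = max_lv
    predictions = np.full((n, max_lv), np.nan)
    for f in range(plan.n_splits):
        test = folds == f
        train = ~test
        if recipe is not None:
            fitted = recipe.fit(X.subset(np.asarray(X.sample_ids)[train]))
            X_train = fitted.apply(
                X.subset(np.asarray(X.sample_ids)[train])).reflectance
            X_test = fitted.apply(
                X.subset(np.asarray(X.sample_ids)[test])).reflectance
        else:
            M = _as_matrix(X)
            X_train, X_test = M[train], M[test]
        scale = None
        if autoscale:
            scale = X_train.std(axis=0, ddof=1)
            tol = 100 * np.finfo(float).eps * np.maximum(
                1.0, np.abs(X_train.mean(axis=0)))
            if np.any(scale <= tol):
                raise DegenerateDataError(
                    "zero-variance column inside a training fold")
        k_fold = min(max_lv, np.linalg.matrix_rank(X_train - X_train.mean(0)))
        max_lv_eff = min(max_lv_eff, k_fold)
        model = fit_pls1(X_train, y[train], k_fold, x_scale=scale)
        for k in range(1, k_fold + 1):
            predictions[test, k - 1] = predict(model, X_test, n_lv=k)

    if max_lv_eff < max_lv:
        logger.warning("max_lv reduced from %d to %d by fold rank",
                       max_lv, max_lv_eff)
        predictions = predictions[:, :max_lv_eff]
    rmsecv = np.sqrt(np.nanmean((predictions - y[:, None]) ** 2, axis=0))
    with np.errstate(invalid="ignore"):
        r2 = np.array([
            np.corrcoef(predictions[:, k], y)[0, 1] ** 2
            if np.nanstd(predictions[:, k]) > 0 else 0.0
            for k in range(predictions.shape[1])])
    n_lv = choose_n_lv(rmsecv, epsilon)
    return CrossValResult(rmsecv, r2, n_lv, predictions, folds, epsilon)


def cross_validate_plsda(X, labels, n_lv: int, plan: CrossValPlan,
                         threshold: float = 0.5) -> dict:
    """Calibration and cross-validated sensitivity/specificity for PLS-DA."""
    labels = np.asarray(labels)
    M = _as_matrix(X)
    model = fit_plsda(M, labels, n_lv, threshold)
    cal = classification_metrics(labels, classify(model, M), model.classes)
    folds = venetian_blinds(len(labels), plan)
    cv_pred = np.empty(len(labels), dtype=labels.dtype)
    for f in np.unique(folds):
        test = folds == f
        if len(np.unique(labels[~test])) < 2:
            raise DegenerateDataError(
                "a training fold contains a single class")
        sub = fit_plsda(M[~test], labels[~test], n_lv, threshold)
        cv_pred[test] = classify(sub, M[test])
    cv = classification_metrics(labels, cv_pred, model.classes)
    return {"model": model, "calibration": cal, "cross_validation": cv,
            "cv_predictions": cv_pred}


# ---------------------------------------------------------------------------
# Kennard-Stone

def kennard_stone(X, n_select: int) -> np.ndarray:
    """Classic maximin sample selection (Euclidean distances).

    Starts from the two mutually most distant samples and repeatedly adds
    the sample whose minimum distance to the selected set is largest.  Ties
    are broken by the lowest index, so the output is deterministic.
    """
    M = _as_matrix(X)
    n = M.shape[0]
    if not 2 <= n_select <= n:
        raise ConfigurationError(f"n_select must be in [2, {n}]")
    D = squareform(pdist(M))
    start = np.unravel_index(np.argmax(D), D.shape)  # lowest-index pair wins
    selected = [min(start), max(start)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    while len(selected) < n_select:
        min_dist[selected] = -1.0
        nxt = int(np.argmax(min_dist))    # argmax takes the lowest index on ties
        selected.append(nxt)
        min_dist = np.minimum(min_dist, D[nxt])
    return np.array(sorted(selected))


def kennard_stone_split(X, train_fraction: float = 2 / 3,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Training/test split with ~train_fraction of samples in training."""
    n = _as_matrix(X).shape[0]
    n_train = int(round(train_fraction * n))
    train = kennard_stone(X, n_train)
    test = np.setdiff1d(np.arange(n), train)
    return train, test


# ---------------------------------------------------------------------------
# Variable selection

@dataclass
class SelectionResult:
    """Outcome of a variable-selection run."""

    method: str
    indices: np.ndarray            # unique, sorted column indices
    scores: np.ndarray             # per-variable method-specific score
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise DegenerateDataError(f"{self.method} selected no variables")
        if np.unique(self.indices).size != self.indices.size:
            raise ConfigurationError("selected indices must be unique")


def vip(model: PLSModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_k ssy_k (w_jk / ||w_k||)^2 / sum_k ssy_k) with
    ssy_k the y sum-of-squares explained by LV k.  mean(VIP^2) = 1.
    """
    ssy = model.y_variance_explained_pct
    total = ssy.sum()
    if total <= 0:
        raise DegenerateDataError("model explains no y-variance")
    p = model.W.shape[0]
    w_norm2 = (model.W ** 2) / (model.W ** 2).sum(axis=0)
    return np.sqrt(p * (w_norm2 * ssy).sum(axis=1) / total)


def selectivity_ratio(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Selectivity ratio from target projection.

    X (the matrix the model was fitted on, same pre-treatment) is projected
    onto the normalised regression vector; per variable the ratio of
    explained to residual variance along that projection is returned.
    Variables with zero residual variance get ``inf``.
    """
    b = model.b
    nb = np.linalg.norm(b)
    if nb <= 0:
        raise DegenerateDataError("regression vector is zero")
    Xc = np.atleast_2d(np.asarray(X, float)) - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    t = Xc @ (b / nb)
    p_tp = Xc.T @ t / float(t @ t)
    explained = np.outer(t, p_tp)
    residual = Xc - explained
    ss_exp = (explained ** 2).sum(axis=0)
    ss_res = (residual ** 2).sum(axis=0)
    with np.errstate(divide="ignore"):
        return np.where(ss_res > 0, ss_exp / np.where(ss_res > 0, ss_res, 1.0),
                        np.inf)


def make_intervals(n_variables: int, interval_count: int) -> list[np.ndarray]:
    """Split column indices into contiguous, nearly equal intervals."""
    if interval_count < 2:
        raise ConfigurationError("interval_count must be >= 2")
    if n_variables < interval_count:
        raise ConfigurationError("more intervals than variables")
    edges = np.linspace(0, n_variables, interval_count + 1).round().astype(int)
    return [np.arange(edges[i], edges[i + 1]) for i in range(interval_count)]


def ipls(X, y: np.ndarray, interval_count: int, max_lv: int,
         plan: CrossValPlan, min_improvement: float = 0.01,
         epsilon: float = 0.02) -> SelectionResult:
    """Forward interval PLS.

    The wavelength grid is cut into contiguous intervals; selection starts
    from the single best interval (lowest RMSECV at its chosen LV count) and
    greedily adds the interval that most lowers RMSECV, stopping when no
    addition improves it by more than ``min_improvement`` (relative).
    ``X`` should already carry the pre-treatment (intervals of a derivative
    spectrum are selected, not derivatives of intervals).
    """
    M = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    intervals = make_intervals(M.shape[1], interval_count)

    def score(cols: np.ndarray) -> float:
        k = min(max_lv, cols.size)
        return cross_validate(M[:, cols], y, None, k, plan,
                              epsilon).rmsecv_selected

    per_interval = np.array([score(iv) for iv in intervals])
    chosen = [int(np.argmin(per_interval))]
    best = float(per_interval[chosen[0]])
    remaining = [i for i in range(len(intervals)) if i not in chosen]
    while remaining:
        cols_of = lambda sel: np.concatenate([intervals[i] for i in sorted(sel)])
        trial = [(score(cols_of(chosen + [j])), j) for j in remaining]
        trial_best, j_best = min(trial)
        if trial_best >= best * (1.0 - min_improvement):
            break
        chosen.append(j_best)
        remaining.remove(j_best)
        best = float(trial_best)
    indices = np.concatenate([intervals[i] for i in sorted(chosen)])
    scores_per_var = np.full(M.shape[1], np.nan)
    for i, iv in enumerate(intervals):
        scores_per_var[iv] = per_interval[i]
    return SelectionResult("iPLS", np.sort(indices), scores_per_var,
                           {"intervals": chosen, "rmsecv": best,
                            "interval_rmsecv": per_interval})


def rpls(X, y: np.ndarray, n_lv: int, max_iter: int = 50,
         floor: float = 1e-6) -> SelectionResult:
    """Recursive reweighted PLS.

    Columns are repeatedly multiplied by |b| normalised to max 1 and the
    model refitted; weights concentrate on informative variables.  Variables
    whose cumulative weight falls below ``floor`` are dropped.  Stops when
    the active set is stable; raises on divergence or full collapse.
    """
    M = _as_matrix(X)
    y = np.asarray(y, float).ravel()
    p = M.shape[1]
    g = np.ones(p)
    active = np.arange(p)
    trace: list[int] = []
    entropy: list[float] = []
    for _ in range(max_iter):
        Xw = M[:, active] * g[active]
        k = min(n_lv, np.linalg.matrix_rank(Xw - Xw.mean(axis=0)))
        if k < 1:
            raise DegenerateDataError(
                f"rPLS collapsed to rank 0 (trace of active sizes: {trace})")
        model = fit_pls1(Xw, y, k)
        w = np.abs(model.b)
        if w.max() <= 0:
            raise DegenerateDataError(
                f"rPLS produced a zero regression vector (trace: {trace})")
        g_prev = g.copy()
        g[active] = g[active] * w / w.max()
        new_active = active[g[active] >= floor]
        if new_active.size == 0:
            raise DegenerateDataError(
                f"rPLS dropped every variable (trace: {trace})")
        q = g[new_active] / g[new_active].sum()
        entropy.append(float(-(q * np.log(q + 1e-300)).sum()))
        trace.append(new_active.size)
        active = new_active
        # converged once the active set has been stable for three rounds
        # and the surviving weights have essentially stopped moving
        stable_set = len(trace) >= 3 and trace[-1] == trace[-2] == trace[-3]
        stable_w = np.max(np.abs(g - g_prev)) < 1e-9
        if stable_set or stable_w:
            break
    else:
        raise DegenerateDataError(
            f"rPLS did not stabilise in {max_iter} iterations "
            f"(trace of active sizes: {trace})")
    return SelectionResult("rPLS", np.sort(active), g,
                           {"iterations": len(trace), "trace": trace,
                            "entropy": entropy})


def vip_select(model: PLSModel, threshold: float = 1.0) -> SelectionResult:
    """Variables with VIP score above the conventional threshold of 1."""
    scores = vip(model)
    return SelectionResult("VIP", np.flatnonzero(scores >= threshold), scores,
                           {"threshold": threshold})


def sratio_select(model: PLSModel, X, quantile: float = 0.75,
                  ) -> SelectionResult:
    """Variables whose selectivity ratio exceeds the given quantile."""
    scores = selectivity_ratio(model, _as_matrix(X))
    finite = scores[np.isfinite(scores)]
    cut = np.quantile(finite, quantile) if finite.size else 0.0
    return SelectionResult("sRatio", np.flatnonzero(scores >= cut), scores,
                           {"quantile": quantile, "cut": float(cut)})
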