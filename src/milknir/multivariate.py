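"""Latent-variable engines: PCA, PLS1 (NIPALS), PLS-DA, leverage.

The PLS1 implementation is classic NIPALS with X-deflation: at each latent
variable the weight vector is the normalised covariance direction
``w = X'y / ||X'y||``, scores ``t = Xw``, X-loadings ``p = X't / t't``,
y-loading ``q = y't / t't``, and X is deflated by ``t p'``.  The regression
vector is ``b = W (P'W)^-1 q``.  Data are mean-centred internally; optional
column scaling (autoscaling) is supported through ``x_scale``.

Loading/weight signs follow the convention that each vector's
largest-magnitude element is positive, so repeated runs are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, DegenerateDataError


def _fix_sign(v: np.ndarray) -> float:
    """Return the sign that makes the largest-|.| element of v positive."""
    return 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Principal components of a mean-centred matrix (via SVD)."""

    n_pc: int
    mean: np.ndarray               # (p,)
    loadings: np.ndarray           # (p, k), orthonormal columns
    scores: np.ndarray             # (n, k)
    explained_variance_pct: np.ndarray  # (k,), percent of total variance

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.mean.size:
            raise ConfigurationError("PCA grid mismatch")
        return (X - self.mean) @ self.loadings


def fit_pca(X: np.ndarray, n_pc: int) -> PCAModel:
    """PCA on mean-centred data; variance percentages refer to total."""
    X = np.atleast_2d(np.asarray(X, float))
    n, p = X.shape
    if not 1 <= n_pc <= min(n - 1, p):
        raise ConfigurationError(
            f"n_pc must be in [1, {min(n - 1, p)}], got {n_pc}")
    mean = X.mean(axis=0)
    Xc = X - mean
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    if total <= 0:
        raise DegenerateDataError("PCA input has zero variance")
    loadings = vt[:n_pc].T.copy()
    scores = u[:, :n_pc] * s[:n_pc]
    for k in range(n_pc):
        sign = _fix_sign(loadings[:, k])
        loadings[:, k] *= sign
        scores[:, k] *= sign
    explained = 100.0 * s[:n_pc] ** 2 / total
    return PCAModel(n_pc, mean, loadings, scores, explained)


# ---------------------------------------------------------------------------
# PLS1

@dataclass
class PLSModel:
    """Fitted PLS1 calibration.

    ``W`` x-weights, ``P`` x-loadings, ``T`` x-scores, ``q`` y-loadings,
    one column/entry per latent variable; ``b`` is the regression vector for
    the full model.  ``y_variance_explained_pct`` is the percent of centred
    y sum-of-squares captured per LV (cumulative sum is non-decreasing).
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray | None
    W: np.ndarray                  # (p, k)
    P: np.ndarray                  # (p, k)
    T: np.ndarray                  # (n, k)
    q: np.ndarray                  # (k,)
    b: np.ndarray                  # (p,)
    y_variance_explained_pct: np.ndarray  # (k,)

    @property
    def n_train(self) -> int:
        return self.T.shape[0]

    def coefficients(self, n_lv: int | None = None) -> np.ndarray:
        """Regression vector using the first ``n_lv`` latent variables."""
        k = self.n_lv if n_lv is None else int(n_lv)
        if not 1 <= k <= self.n_lv:
            raise ConfigurationError(f"n_lv must be in [1, {self.n_lv}]")
        W, P, q = self.W[:, :k], self.P[:, :k], self.q[:k]
        return W @ np.linalg.solve(P.T @ W, q)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int,
             x_scale: np.ndarray | None = None) -> PLSModel:
    """PLS1 via NIPALS with X-deflation.

    Parameters
    ----------
    X : (n, p) matrix (already pre-treated; centring is internal).
    y : (n,) response.
    n_lv : number of latent variables, at most rank(X after centring).
    x_scale : optional per-column divisors applied after centring
        (autoscaled PLS passes the training column SDs).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ConfigurationError("X and y have different sample counts")
    if np.std(y) == 0:
        raise DegenerateDataError("y has zero variance")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if x_scale is not None:
        x_scale = np.asarray(x_scale, float)
        if np.any(x_scale <= 0):
            raise ConfigurationError("x_scale entries must be positive")
        Xc = Xc / x_scale
    rank = np.linalg.matrix_rank(Xc)
    if not 1 <= n_lv <= rank:
        raise ConfigurationError(
            f"n_lv must be in [1, rank {rank}], got {n_lv}")
    y_mean = float(y.mean())
    yc = y - y_mean
    ss_y = float(yc @ yc)

    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    T = np.empty((n, n_lv))
    q = np.empty(n_lv)
    Xd = Xc.copy()
    for k in range(n_lv):
        w = Xd.T @ yc
        norm = np.linalg.norm(w)
        if norm <= 1e-14 * max(1.0, np.abs(yc).max()):
            raise DegenerateDataError(
                f"no covariance left for latent variable {k + 1}")
        w = w / norm
        w = w * _fix_sign(w)
        t = Xd @ w
        tt = float(t @ t)
        P[:, k] = Xd.T @ t / tt
        q[k] = float(yc @ t) / tt
        W[:, k] = w
        T[:, k] = t
        Xd = Xd - np.outer(t, P[:, k])
    explained = 100.0 * q ** 2 * (T ** 2).sum(axis=0) / ss_y
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(n_lv, x_mean, y_mean, x_scale, W, P, T, q, b, explained)


def predict(model: PLSModel, X_new: np.ndarray,
            n_lv: int | None = None) -> np.ndarray:
    """Predict the response for new (pre-treated) spectra."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.x_mean.size:
        raise ConfigurationError(
            f"wavelength grid mismatch: model has {model.x_mean.size} "
            f"variables, input has {X_new.shape[1]}")
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    b = model.b if n_lv is None else model.coefficients(n_lv)
    return Xc @ b + model.y_mean


def scores(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Score vectors t for new samples: t = X_c W (P'W)^-1."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.x_mean.size:
        raise ConfigurationError("wavelength grid mismatch")
    Xc = X_new - model.x_mean
    if model.x_scale is not None:
        Xc = Xc / model.x_scale
    R = model.W @ np.linalg.inv(model.P.T @ model.W)
    return Xc @ R


def leverage(model: PLSModel, X_new: np.ndarray | None = None) -> np.ndarray:
    """Leverage h = t' (T'T)^-1 t in the model's score space.

    With ``X_new=None`` the training-sample leverages are returned; their
    mean is n_lv / n_train (hat-matrix trace identity) and a sample at the
    training mean has h = 0.
    """
    T = model.T
    TtT = T.T @ T
    cond = np.linalg.cond(TtT)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateDataError("singular score covariance")
    t = T if X_new is None else scores(model, X_new)
    return np.einsum("ij,jk,ik->i", t, np.linalg.inv(TtT), t)


def flag_outliers(model: PLSModel, X: np.ndarray, y: np.ndarray,
                  residual_limit: float = 3.0,
                  leverage_factor: float = 3.0) -> pd.DataFrame:
    """Flag calibration outlier *candidates* — never remove them silently.

    A sample is flagged when its studentised y-residual exceeds
    ``residual_limit`` or its leverage exceeds
    ``leverage_factor * n_lv / n``.  Dropping flagged samples is an explicit
    user decision.
    """
    y = np.asarray(y, float).ravel()
    resid = y - predict(model, X)
    sd = resid.std(ddof=model.n_lv + 1) if len(y) > model.n_lv + 1 else resid.std()
    student = resid / sd if sd > 0 else np.zeros_like(resid)
    h = leverage(model, X)
    limit_h = leverage_factor * model.n_lv / len(y)
    return pd.DataFrame({
        "residual": resid,
        "studentized_residual": student,
        "leverage": h,
        "flagged": (np.abs(student) > residual_limit) | (h > limit_h),
    })


# ---------------------------------------------------------------------------
# PLS-DA

@dataclass
class ClassModel:
    """PLS-DA: PLS1 on a 0/1 dummy response plus a decision threshold."""

    pls: PLSModel
    threshold: float
    classes: tuple = ("0", "1")    # classes[0] -> dummy 0, classes[1] -> 1

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must be in (0, 1)")


def fit_plsda(X: np.ndarray, labels, n_lv: int,
              threshold: float = 0.5) -> ClassModel:
    """Fit a two-class PLS-DA model (dummy y in {0, 1})."""
    labels = np.asarray(labels)
    classes = tuple(sorted(pd.unique(labels), key=str))
    if len(classes) != 2:
        raise ConfigurationError(
            f"PLS-DA requires exactly two classes, got {len(classes)}")
    y = (labels == classes[1]).astype(float)
    return ClassModel(fit_pls1(X, y, n_lv), threshold, classes)


def classify(model: ClassModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted class labels: dummy prediction >= threshold -> class 1."""
    yhat = predict(model.pls, X_new)
    return np.where(yhat >= model.threshold, model.classes[1],
                    model.classes[0])


def classification_metrics(labels_true, labels_pred,
                           classes: tuple) -> pd.DataFrame:
    """Per-class sensitivity and specificity for a two-class problem."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    rows = []
    for cls in classes:
        is_cls = labels_true == cls
        pred_cls = labels_pred == cls
        sens = float(np.mean(pred_cls[is_cls])) if is_cls.any() else np.nan
        spec = (float(np.mean(~pred_cls[~is_cls]))
                if (~is_cls).any() else np.nan)
        rows.append({"class": cls, "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model bundle serialisation (YAML metadata + CSV arrays)

def save_model(model: PLSModel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_lv": int(model.n_lv),
        "y_mean": float(model.y_mean),
        "scaled": model.x_scale is not None,
        "y_variance_explained_pct":
            [float(v) for v in model.y_variance_explained_pct],
    }
    (d / "model.yaml").write_text(yaml.safe_dump(meta))
    arrays = {"W": model.W, "P": model.P, "T": model.T,
              "q": model.q[:, None], "b": model.b[:, None],
              "x_mean": model.x_mean[:, None]}
    if model.x_scale is not None:
        arrays["x_scale"] = model.x_scale[:, None]
    for name, arr in arrays.items():
        np.savetxt(d / f"{name}.csv", arr, delimiter=",")


def load_model(directory: str | Path) -> PLSModel:
    d = Path(directory)
    meta = yaml.safe_load((d / "model.yaml").read_text())
    load = lambda name: np.atleast_2d(np.loadtxt(d / f"{name}.csv",
                                                 delimiter=",", ndmin=2))
    W, P, T = load("W"), load("P"), load("T")
    q = load("q").ravel()
    b = load("b").ravel()
    x_mean = load("x_mean").ravel()
    x_scale = load("x_scale").ravel() if meta.get("scaled") else None
    return PLSModel(meta["n_lv"], x_mean, meta["y_mean"], x_scale,
                    W, P, T, q, b,
                    np.asarray(meta["y_variance_explained_pct"], float))
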