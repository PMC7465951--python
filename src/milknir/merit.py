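"""Figures of merit and statistical validation of calibrations.

Covers the error summaries (RMSEC/RMSECV/RMSEP, r^2), the multivariate
limit of detection LOD = Delta(alpha, beta, nu) * RMSEC * sqrt(1 + h0)
built from the calibration error and the leverage h0 of a hypothetical
zero-concentration sample, the confidence interval of the
predicted-vs-measured regression intercept (systematic-error check), and
the elliptical joint confidence region for (intercept, slope) used to
compare two prediction sets against the ideal point (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, DegenerateDataError
from .multivariate import PLSModel, leverage


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root mean square error between measured and predicted values."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size != y_hat.size:
        raise ConfigurationError("length mismatch between y and y_hat")
    if y.size < 2:
        raise ConfigurationError("need at least 2 values")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def rsq(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Squared Pearson correlation between predicted and measured values."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if y.size != y_hat.size:
        raise ConfigurationError("length mismatch between y and y_hat")
    if np.std(y) == 0:
        raise DegenerateDataError("y has zero variance")
    if np.std(y_hat) == 0:
        return 0.0
    return float(np.corrcoef(y, y_hat)[0, 1] ** 2)


def estimate_h0(model: PLSModel, target_values: np.ndarray,
                k_lowest: int = 5) -> float:
    """Zero-concentration leverage h0.

    Estimated as the mean training-set leverage of the ``k_lowest`` samples
    with the smallest target concentration — a practical stand-in for the
    leverage of a sample at exactly zero concentration.
    """
    target_values = np.asarray(target_values, float).ravel()
    n = model.n_train
    if target_values.size != n:
        raise ConfigurationError("target_values length must match training set")
    if not 1 <= k_lowest <= n:
        raise ConfigurationError(f"k_lowest must be in [1, {n}]")
    h = leverage(model)
    lowest = np.argsort(target_values, kind="stable")[:k_lowest]
    return float(h[lowest].mean())


def detection_factor(alpha: float = 0.05, beta: float = 0.05,
                     df: int | None = None) -> float:
    """Delta(alpha, beta, nu) for the multivariate LOD.

    For nu >= 25 (or unspecified) the practical constant 2 is used; the
    exact small-sample option sums the one-sided t quantiles for the false
    positive (alpha) and false negative (beta) risks.
    """
    if df is None or df >= 25:
        return 2.0
    if df < 1:
        raise ConfigurationError("df must be >= 1")
    return float(stats.t.ppf(1 - alpha, df) + stats.t.ppf(1 - beta, df))


def multivariate_lod(rmsec: float, h0: float, alpha: float = 0.05,
                     beta: float = 0.05, df: int | None = None) -> float:
    """LOD = Delta(alpha, beta, nu) * RMSEC * sqrt(1 + h0)."""
    if rmsec <= 0:
        raise ConfigurationError("rmsec must be positive")
    if h0 < 0:
        raise ConfigurationError("h0 must be nonnegative")
    return detection_factor(alpha, beta, df) * rmsec * np.sqrt(1.0 + h0)


@dataclass
class InterceptTest:
    """CI for the intercept of the predicted-vs-measured regression."""

    b0: float
    s_b0: float
    lower: float
    upper: float
    contains_zero: bool
    slope: float
    alpha: float
    df: int


def intercept_ci(y_measured: np.ndarray, y_predicted: np.ndarray,
                 alpha: float = 0.05) -> InterceptTest:
    """Systematic-error check: does the intercept CI include zero?

    OLS of predicted on measured; two-sided t interval with n - 2 degrees
    of freedom on the intercept.
    """
    x = np.asarray(y_measured, float).ravel()
    y = np.asarray(y_predicted, float).ravel()
    if x.size != y.size or x.size < 3:
        raise ConfigurationError("need >= 3 paired values")
    if np.std(x) == 0:
        raise DegenerateDataError("measured values have zero variance")
    fit = stats.linregress(x, y)
    df = x.size - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    lower = fit.intercept - t_crit * fit.intercept_stderr
    upper = fit.intercept + t_crit * fit.intercept_stderr
    return InterceptTest(float(fit.intercept), float(fit.intercept_stderr),
                         float(lower), float(upper),
                         bool(lower <= 0.0 <= upper), float(fit.slope),
                         alpha, df)


@dataclass
class JointCITest:
    """Elliptical joint confidence region for (intercept, slope).

    The region is {beta : (beta - beta_hat)' X'X (beta - beta_hat)
    <= 2 s^2 F(alpha; 2, n-2)} from the two-parameter F statistic of the
    regression of set b on set a.  ``contains_point_0_1`` reports whether
    the ideal agreement point (intercept 0, slope 1) lies inside.
    """

    intercept: float
    slope: float
    xtx: np.ndarray                # (2, 2) moment matrix of [1, a]
    bound: float                   # 2 * s^2 * F_crit
    contains_point_0_1: bool
    alpha: float
    df: int

    def contains(self, intercept: float, slope: float) -> bool:
        d = np.array([intercept - self.intercept, slope - self.slope])
        # absolute slack floors the comparison for numerically perfect fits
        # (zero residual variance makes the bound collapse to rounding noise)
        slack = 1e-12 * np.trace(self.xtx) * (1.0 + d @ d)
        return bool(d @ self.xtx @ d <= self.bound + slack)

    def ellipse_points(self, n: int = 200) -> np.ndarray:
        """Boundary points (n, 2) for plotting."""
        L = np.linalg.cholesky(self.xtx / self.bound)
        theta = np.linspace(0, 2 * np.pi, n)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        return (np.linalg.solve(L.T, circle).T
                + np.array([self.intercept, self.slope]))


def joint_ci_test(set_a: np.ndarray, set_b: np.ndarray,
                  alpha: float = 0.05) -> JointCITest:
    """Method comparison via the joint (intercept, slope) confidence region.

    Regresses set b on set a and tests whether (0, 1) lies inside the
    100(1-alpha)% elliptical confidence region; if it does, the two sets of
    predictions are statistically indistinguishable at that level.
    """
    a = np.asarray(set_a, float).ravel()
    b = np.asarray(set_b, float).ravel()
    if a.size != b.size or a.size < 3:
        raise ConfigurationError("need >= 3 paired values")
    if np.std(a) == 0:
        raise DegenerateDataError("set_a has zero variance")
    n = a.size
    X = np.column_stack([np.ones(n), a])
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ b)
    resid = b - X @ beta
    df = n - 2
    s2 = float(resid @ resid) / df
    f_crit = stats.f.ppf(1 - alpha, 2, df)
    bound = 2.0 * s2 * f_crit
    test = JointCITest(float(beta[0]), float(beta[1]), xtx, bound, False,
                       alpha, df)
    test.contains_point_0_1 = test.contains(0.0, 1.0)
    return test


@dataclass
class MeritReport:
    """Bundle of figures of merit for one calibration."""

    property_name: str
    n_lv: int
    rmsec: float
    rmsecv: float | None = None
    rmsep: float | None = None
    r2_cal: float | None = None
    r2_cv: float | None = None
    r2_pred: float | None = None
    h0: float | None = None
    delta: float | None = None
    lod: float | None = None
    intercept_test: InterceptTest | None = None
    joint_test: JointCITest | None = None
    below_lod: np.ndarray | None = None   # detect-only flags per prediction

    def flag_below_lod(self, predictions: np.ndarray) -> np.ndarray:
        """Mark predictions below the LOD as detect-only (no censoring)."""
        if self.lod is None:
            raise ConfigurationError("LOD has not been computed")
        self.below_lod = np.asarray(predictions, float) < self.lod
        return self.below_lod


def merit_report(property_name: str, model: PLSModel, y: np.ndarray,
                 y_hat_cal: np.ndarray, y_hat_cv: np.ndarray | None = None,
                 k_lowest: int = 5, alpha: float = 0.05,
                 beta: float = 0.05) -> MeritReport:
    """Assemble the standard merit block for a fitted calibration."""
    y = np.asarray(y, float).ravel()
    rmsec = rmse(y, y_hat_cal)
    h0 = estimate_h0(model, y, k_lowest)
    df = model.n_train - model.n_lv - 1
    report = MeritReport(
        property_name=property_name, n_lv=model.n_lv, rmsec=rmsec,
        r2_cal=rsq(y, y_hat_cal), h0=h0,
        delta=detection_factor(alpha, beta, df),
        lod=multivariate_lod(rmsec, h0, alpha, beta, df))
    if y_hat_cv is not None:
        report.rmsecv = rmse(y, y_hat_cv)
        report.r2_cv = rsq(y, y_hat_cv)
        report.intercept_test = intercept_ci(y, y_hat_cv, alpha)
    return report
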