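"""Spectral pre-treatments: Savitzky-Golay, SNV, MSC, centring/scaling.

All operations take and return :class:`~milknir.io.SpectralBlock` objects and
never alter the wavelength grid or the row order.  Treatments that learn
statistics from data (MSC reference, column means/SDs) are *fitted* on a
training block and then *applied* unchanged to new data, so cross-validation
can refit them inside each fold without leakage.  An ordered
:class:`PreprocessRecipe` composes the steps; order matters and is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .exceptions import ConfigurationError, DegenerateDataError
from .io import SpectralBlock


def savitzky_golay(block: SpectralBlock, window: int, polyorder: int,
                   deriv: int = 0) -> SpectralBlock:
    """Savitzky-Golay smoothing / differentiation along the wavelength axis.

    Derivatives are scaled by the grid step so they are per-nm.  Edges are
    handled by fitting the terminal-window polynomial and evaluating it at
    the edge points, so the output grid equals the input grid.  Requires an
    (approximately) uniform wavelength grid.
    """
    if window % 2 == 0:
        raise ConfigurationError(f"window must be odd, got {window}")
    if not 3 <= window <= block.n_wavelengths:
        raise ConfigurationError(
            f"window must be in [3, {block.n_wavelengths}], got {window}")
    if polyorder >= window:
        raise ConfigurationError("polyorder must be smaller than window")
    if deriv > polyorder:
        raise ConfigurationError(
            f"derivative order {deriv} exceeds polynomial order {polyorder}")
    steps = np.diff(block.wavelengths)
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise ConfigurationError("Savitzky-Golay requires a uniform grid")
    out = savgol_filter(block.reflectance, window_length=window,
                        polyorder=polyorder, deriv=deriv, delta=steps[0],
                        axis=1, mode="interp")
    return block.with_reflectance(out)


def savgol_coefficients(window: int, polyorder: int, deriv: int,
                        delta: float = 1.0) -> np.ndarray:
    """Central filter weights (for property checks: sums are 1 or 0)."""
    from scipy.signal import savgol_coeffs
    return savgol_coeffs(window, polyorder, deriv=deriv, delta=delta,
                         use="dot")


def snv(block: SpectralBlock) -> SpectralBlock:
    """Standard normal variate: centre and scale each spectrum to SD 1."""
    x = block.reflectance
    sd = x.std(axis=1, ddof=1)
    flat = np.flatnonzero(sd <= 0)
    if flat.size:
        raise DegenerateDataError(
            f"SNV undefined for constant spectrum of sample "
            f"{block.sample_ids[flat[0]]!r}")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return block.with_reflectance(out)


def msc(block: SpectralBlock,
        reference: np.ndarray | str = "mean") -> SpectralBlock:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference (x ~ a + b*ref) and
    replaced by (x - a) / b.  ``reference="mean"`` uses the block's own mean
    spectrum; pass an explicit vector (e.g. a training-set mean) to correct
    new data without leakage.
    """
    if isinstance(reference, str):
        if reference != "mean":
            raise ConfigurationError(f"unknown MSC reference {reference!r}")
        ref = block.reflectance.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (block.n_wavelengths,):
            raise ConfigurationError("MSC reference grid mismatch")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom <= 0:
        raise DegenerateDataError("MSC reference spectrum is constant")
    x = block.reflectance
    slope = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    zero = np.flatnonzero(slope == 0)
    if zero.size:
        raise DegenerateDataError(
            f"MSC slope is zero for sample {block.sample_ids[zero[0]]!r}")
    intercept = x.mean(axis=1) - slope * ref.mean()
    out = (x - intercept[:, None]) / slope[:, None]
    return block.with_reflectance(out)


@dataclass
class CenterScaleStats:
    """Column statistics learned on a training block."""

    mode: str                  # "mean-center" | "autoscale"
    mean: np.ndarray
    sd: np.ndarray | None = None


def fit_center_scale(train: SpectralBlock, mode: str = "mean-center",
                     ) -> CenterScaleStats:
    """Learn column means (and SDs for autoscaling) from a training block."""
    if mode not in ("mean-center", "autoscale"):
        raise ConfigurationError(f"unknown centring mode {mode!r}")
    if train.n_samples == 0:
        raise ConfigurationError("training block is empty")
    mean = train.reflectance.mean(axis=0)
    sd = None
    if mode == "autoscale":
        sd = train.reflectance.std(axis=0, ddof=1)
        # a numerically constant column has sd at rounding level, not 0
        tol = 100 * np.finfo(float).eps * np.maximum(1.0, np.abs(mean))
        flat = np.flatnonzero(sd <= tol)
        if flat.size:
            raise DegenerateDataError(
                f"zero-variance column at {train.wavelengths[flat[0]]:g} nm "
                f"cannot be autoscaled")
    return CenterScaleStats(mode, mean, sd)


def apply_center_scale(stats: CenterScaleStats,
                       block: SpectralBlock) -> SpectralBlock:
    """Apply training-set centring/scaling statistics to any block."""
    if stats.mean.shape != (block.n_wavelengths,):
        raise ConfigurationError("centring statistics grid mismatch")
    out = block.reflectance - stats.mean
    if stats.mode == "autoscale":
        out = out / stats.sd
    return block.with_reflectance(out)


# ---------------------------------------------------------------------------
# Recipes

_STATELESS = ("savgol", "snv")
_STATEFUL = ("msc", "mean-center", "autoscale")


@dataclass
class PreprocessRecipe:
    """Ordered list of pre-treatment steps.

    Each step is a ``{"kind": ..., **params}`` mapping.  Supported kinds:
    ``savgol`` (window, polyorder, deriv), ``snv``, ``msc`` (reference
    learned at fit time), ``mean-center``, ``autoscale``.  Stateful steps
    learn their statistics in :meth:`fit`, which returns a
    :class:`FittedRecipe` usable on new data.
    """

    steps: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        for step in self.steps:
            kind = step.get("kind")
            if kind not in _STATELESS + _STATEFUL:
                raise ConfigurationError(f"unknown preprocessing step {kind!r}")
            if kind == "savgol":
                window = int(step.get("window", 15))
                polyorder = int(step.get("polyorder", 1))
                deriv = int(step.get("deriv", 0))
                if window % 2 == 0 or window < polyorder + 1:
                    raise ConfigurationError(
                        f"savgol window {window} must be odd and "
                        f">= polyorder + 1")
                if deriv > polyorder:
                    raise ConfigurationError(
                        "savgol derivative order exceeds polynomial order")

    def fit(self, train: SpectralBlock) -> "FittedRecipe":
        fitted_steps: list[tuple[dict, object]] = []
        current = train
        for step in self.steps:
            kind = step["kind"]
            state: object = None
            if kind == "msc":
                state = current.reflectance.mean(axis=0)
            elif kind in ("mean-center", "autoscale"):
                state = fit_center_scale(current, kind)
            fitted_steps.append((step, state))
            current = _apply_step(step, state, current)
        return FittedRecipe(fitted_steps)

    def fit_apply(self, train: SpectralBlock) -> SpectralBlock:
        return self.fit(train).apply(train)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PreprocessRecipe":
        with open(path) as fh:
            data = yaml.safe_load(fh) or []
        if isinstance(data, dict):
            data = data.get("steps", [])
        return cls(list(data))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({"steps": self.steps}))


@dataclass
class FittedRecipe:
    """A recipe with all learned statistics frozen to its training set."""

    fitted_steps: list[tuple[dict, object]]

    def apply(self, block: SpectralBlock) -> SpectralBlock:
        current = block
        for step, state in self.fitted_steps:
            current = _apply_step(step, state, current)
        return current


def _apply_step(step: dict, state: object,
                block: SpectralBlock) -> SpectralBlock:
    kind = step["kind"]
    if kind == "savgol":
        return savitzky_golay(block, int(step.get("window", 15)),
                              int(step.get("polyorder", 1)),
                              int(step.get("deriv", 0)))
    if kind == "snv":
        return snv(block)
    if kind == "msc":
        return msc(block, state)
    if kind in ("mean-center", "autoscale"):
        return apply_center_scale(state, block)
    raise ConfigurationError(f"unknown preprocessing step {kind!r}")


# The short-wave instrument's standard treatment: first-order polynomial
# smoothing over 15 points followed by a second derivative (the derivative
# pass uses polyorder 2, since a first-order polynomial carries no second
# derivative).  The long-wave instrument uses smoothing alone.
SHORTWAVE_RECIPE = PreprocessRecipe([
    {"kind": "savgol", "window": 15, "polyorder": 1, "deriv": 0},
    {"kind": "savgol", "window": 15, "polyorder": 2, "deriv": 2},
])
LONGWAVE_RECIPE = PreprocessRecipe([
    {"kind": "savgol", "window": 15, "polyorder": 1, "deriv": 0},
])
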