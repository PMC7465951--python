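"""Synthetic milk compositions and two-instrument NIR reflectance spectra.

The generator emulates the statistical structure of a commercial-milk NIR
study: ~45 UHT milks spanning the retail range of fat (0.1-3.7 g/100 mL),
protein (1.3-7 g/100 mL) and carbohydrate (2.5-13.5 g/100 mL), measured in
diffuse reflectance on two pocket spectrometers — a low-noise short-wave
unit (331 points, 740-1070 nm) and a noisier long-wave unit (134 points,
1350-2558 nm).

Milk reflectance is dominated by scattering from fat globules (with a small
contribution from protein micelles), so the simulated spectrum is a smooth
fat-monotone scattering baseline from which strong water absorption dips
(970, 1450, 1950, ~2450 nm) and weak macronutrient absorption bands are
subtracted.  With noise disabled, reflectance at every wavelength is an
affine function of the (fat, protein, carbohydrate) vector — a property the
test suite exploits.  Each sample is measured in triplicate and the three
replicates averaged, as routine practice dictates.

Reference values come from supermarket labels, so the generator can corrupt
true compositions with a bounded uniform labelling error and round to one
decimal, mimicking declared nutritional values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .exceptions import ConfigurationError
from .io import SpectralBlock

# EU fat classes for drinking milk (g fat / 100 mL)
SKIMMED_MAX = 0.5
SEMI_RANGE = (1.5, 1.8)
WHOLE_MIN = 3.5

N_REPLICATES = 3


class Band(NamedTuple):
    """One Gaussian absorption band.

    ``amplitude`` is reflectance units per g/100 mL for macronutrient bands
    and absolute reflectance units for water (concentration fixed at 1).
    The ``lactose`` / ``lactose_free`` components scale with carbohydrate
    content but switch on only for the matching lactose status, giving the
    two classes distinct signatures.
    """

    center: float       # nm
    width: float        # Gaussian sigma, nm
    component: str      # fat | protein | carbohydrate | water | lactose | lactose_free
    amplitude: float    # reflectance units (per g/100 mL for nutrients)


# Water dips at the canonical NIR positions; fat bands at the C-H overtone /
# combination wavelengths; protein and carbohydrate/lactose band positions
# are simulator fiction — plausible but freely parameterised, since no
# authoritative per-component band list is encoded here.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band(970, 25, "water", 0.060),
    Band(1450, 40, "water", 0.120),
    Band(1950, 50, "water", 0.150),
    Band(2450, 60, "water", 0.120),
    Band(930, 12, "fat", 0.0070),
    Band(1690, 14, "fat", 0.0060),
    Band(1722, 12, "fat", 0.0050),
    Band(1754, 12, "fat", 0.0050),
    Band(2302, 16, "fat", 0.0060),
    Band(2340, 16, "fat", 0.0060),
    Band(918, 12, "protein", 0.0060),
    Band(1020, 14, "protein", 0.0080),
    Band(2055, 18, "protein", 0.0080),
    Band(2180, 18, "protein", 0.0080),
    Band(985, 14, "carbohydrate", 0.0015),
    Band(2100, 20, "carbohydrate", 0.0020),
    Band(2270, 20, "carbohydrate", 0.0020),
    Band(1005, 10, "lactose", 0.0040),
    Band(2120, 14, "lactose", 0.0040),
    Band(1040, 10, "lactose_free", 0.0040),
    Band(2080, 14, "lactose_free", 0.0040),
)


@dataclass(frozen=True)
class InstrumentProfile:
    """Wavelength grid and noise level of one virtual spectrometer."""

    name: str
    wavelength_start: float
    wavelength_end: float
    n_points: int
    noise_sd: float = 0.0          # per-replicate white detector noise SD
    smooth_noise_fraction: float = 0.3   # correlated drift SD / noise_sd
    scatter_sd: float = 0.0        # per-sample multiplicative scatter variability
    warmup_drift: float = 0.0      # constant reflectance offset

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ConfigurationError("n_points must be >= 2")
        if self.wavelength_end <= self.wavelength_start:
            raise ConfigurationError("wavelength grid must be increasing")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_end,
                           self.n_points)


# The two default virtual instruments: a 331-point short-wave grid
# (740-1070 nm, low noise) and a 134-point long-wave grid (1350-2558 nm)
# noisier by roughly a factor of three.
SHORTWAVE = InstrumentProfile("shortwave", 740.0, 1070.0, 331,
                              noise_sd=0.008, scatter_sd=0.025)
LONGWAVE = InstrumentProfile("longwave", 1350.0, 2558.0, 134,
                             noise_sd=0.020, scatter_sd=0.025)


@dataclass(frozen=True)
class BaselineCoefficients:
    """Scattering baseline: shape(lambda)*(a + b*fat + c*protein)
    minus an optional multiple-scattering saturation term
    b2 * fat^2 * sat_shape(lambda).

    ``b`` dominates ``c`` because milk's light scattering is largely due to
    fat globules, with a small contribution from protein micelles.  The
    concave fat^2 term (off by default) can model saturation of diffuse
    reflectance at high globule concentrations; when used, ``b2`` must stay
    small enough that reflectance remains strictly increasing in fat over
    the retail range.
    """

    a: float = 0.15
    b: float = 0.12     # per g/100 mL fat
    c: float = 0.005    # per g/100 mL protein
    b2: float = 0.0     # per (g/100 mL)^2 fat, saturation strength
    shape_center: float = 1200.0   # nm, logistic midpoint
    shape_width: float = 500.0     # nm, logistic scale
    shape_floor: float = 0.40
    shape_span: float = 0.60
    sat_center: float = 900.0      # nm, saturation signature peak
    sat_width: float = 250.0       # nm, Gaussian sigma

    def shape(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths, float) - self.shape_center) / self.shape_width
        return self.shape_floor + self.shape_span / (1.0 + np.exp(-z))

    def sat_shape(self, wavelengths: np.ndarray) -> np.ndarray:
        w = np.asarray(wavelengths, float)
        return np.exp(-0.5 * ((w - self.sat_center) / self.sat_width) ** 2)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults reproduce the study conditions: 45 samples, retail composition
    ranges, roughly balanced EU fat classes with "no class" fillers spanning
    the whole fat range, protein concentrated between 3 and 4 g/100 mL with
    tails to the extremes, ~20% lactose-free samples, triplicate measurement,
    and labels rounded to one decimal with a small labelling error.
    """

    n_samples: int = 45
    seed: int = 0
    fat_range: tuple[float, float] = (0.1, 3.7)
    protein_range: tuple[float, float] = (1.3, 7.0)
    carb_range: tuple[float, float] = (2.5, 13.5)
    # proportions of skimmed / semi-skimmed / whole / no-class samples
    class_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    lactose_free_fraction: float = 0.20
    lactose_unknown_fraction: float = 0.10
    # fraction of protein (resp. carbohydrate) draws from the bulk interval
    protein_bulk: tuple[float, float] = (3.0, 4.0)
    protein_bulk_fraction: float = 0.8
    carb_bulk: tuple[float, float] = (4.5, 5.5)
    carb_bulk_fraction: float = 0.7
    label_tolerance: float = 0.15  # g/100 mL, uniform labelling error bound
    band_catalog: tuple[Band, ...] = DEFAULT_BANDS
    baseline: BaselineCoefficients = field(default_factory=BaselineCoefficients)

    def __post_init__(self) -> None:
        for name in ("fat_range", "protein_range", "carb_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi <= lo:
                raise ConfigurationError(f"{name} must be a nonnegative interval")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise ConfigurationError("class_mix must be nonnegative and sum to 1")
        if not 0 <= self.lactose_free_fraction <= 1:
            raise ConfigurationError("lactose_free_fraction must be in [0, 1]")
        if self.label_tolerance < 0:
            raise ConfigurationError("label_tolerance must be nonnegative")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")
        for band in self.band_catalog:
            if band.amplitude < 0:
                raise ConfigurationError(
                    f"negative band amplitude at {band.center} nm")


def _class_counts(config: SimulationConfig) -> list[int]:
    """Largest-remainder apportionment of n_samples across the class mix."""
    raw = [p * config.n_samples for p in config.class_mix]
    counts = [int(np.floor(r)) for r in raw]
    remainder = config.n_samples - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def eu_fat_class(fat: float) -> str:
    if fat < SKIMMED_MAX:
        return "skimmed"
    if SEMI_RANGE[0] <= fat <= SEMI_RANGE[1]:
        return "semi-skimmed"
    if fat >= WHOLE_MIN:
        return "whole"
    return "no-class"


def sample_compositions(config: SimulationConfig) -> pd.DataFrame:
    """Draw a synthetic composition table.

    Fat is drawn per EU class according to ``class_mix`` (no-class fillers
    span the full fat range); protein and carbohydrate mix a bulk interval
    with full-range tails; the lactose flag is assigned independently of fat
    class.  Labelled values start as the true values rounded to one decimal;
    apply :func:`perturb_labels` for labelling error.
    """
    rng = np.random.default_rng([config.seed, _salt("compositions")])
    lo, hi = config.fat_range
    intervals = {
        "skimmed": (lo, min(SKIMMED_MAX, hi)),
        "semi-skimmed": (max(lo, SEMI_RANGE[0]), min(hi, SEMI_RANGE[1])),
        "whole": (max(lo, WHOLE_MIN), hi),
        "no-class": (lo, hi),
    }
    counts = _class_counts(config)
    fats: list[float] = []
    for (cls, (a, b)), k in zip(intervals.items(), counts):
        if k == 0:
            continue
        if b <= a:
            raise ConfigurationError(
                f"class_mix requests {cls!r} samples but fat_range "
                f"{config.fat_range} does not intersect its interval")
        fats.extend(rng.uniform(a, b, size=k))
    fats = np.array(fats)
    rng.shuffle(fats)

    protein = _bulk_tail_draw(rng, config.n_samples, config.protein_range,
                              config.protein_bulk, config.protein_bulk_fraction)
    carb = _bulk_tail_draw(rng, config.n_samples, config.carb_range,
                           config.carb_bulk, config.carb_bulk_fraction)

    u = rng.uniform(size=config.n_samples)
    lactose = np.where(
        u < config.lactose_free_fraction, "absent",
        np.where(u < config.lactose_free_fraction + config.lactose_unknown_fraction,
                 "unknown", "present"))

    width = max(2, len(str(config.n_samples)))
    table = pd.DataFrame({
        "sample_id": [f"S{i + 1:0{width}d}" for i in range(config.n_samples)],
        "fat_true": fats,
        "protein_true": protein,
        "carbohydrate_true": carb,
        "fat": np.round(fats, 1),
        "protein": np.round(protein, 1),
        "carbohydrate": np.round(carb, 1),
        "lactose": lactose,
        "eu_fat_class": [eu_fat_class(f) for f in fats],
    })
    return table


def _bulk_tail_draw(rng: np.random.Generator, n: int,
                    full: tuple[float, float], bulk: tuple[float, float],
                    bulk_fraction: float) -> np.ndarray:
    lo = max(full[0], bulk[0])
    hi = min(full[1], bulk[1])
    from_bulk = rng.uniform(size=n) < bulk_fraction
    values = rng.uniform(full[0], full[1], size=n)
    values[from_bulk] = rng.uniform(lo, hi, size=int(from_bulk.sum()))
    return values


def perturb_labels(table: pd.DataFrame, tolerance: float,
                   seed: int | None = None) -> pd.DataFrame:
    """Corrupt labelled values with a bounded uniform error and round.

    Declared label values become ``round(true + U(-tolerance, tolerance), 1)``
    clipped at zero, mimicking supermarket nutrition labels (the legal
    labelling tolerance is an upper bound on this error).  True values are
    retained in the ``*_true`` columns.  When ``seed`` is omitted it is
    derived from the table's sample ids, so the call is deterministic.
    """
    if tolerance < 0:
        raise ConfigurationError("tolerance must be nonnegative")
    if seed is None:
        seed = zlib.crc32("|".join(table["sample_id"].astype(str)).encode())
    rng = np.random.default_rng([seed, _salt("labels")])
    out = table.copy()
    for col in ("fat", "protein", "carbohydrate"):
        true = out[f"{col}_true"].to_numpy(float)
        err = rng.uniform(-tolerance, tolerance, size=len(out))
        out[col] = np.round(np.clip(true + err, 0.0, None), 1)
    return out


def band_contributions(table: pd.DataFrame, wavelengths: np.ndarray,
                       config: SimulationConfig) -> np.ndarray:
    """Closed-form noise-free reflectance model (n_samples x n_wavelengths).

    reflectance = shape(lambda) * (a + b*fat + c*protein)
                  - b2 * fat^2 * sat_shape(lambda)
                  - water_fraction * sum of Gaussian water dips
                  - sum of concentration-scaled macronutrient bands.
    The water-dip depths scale with the sample's water fraction
    (100 - fat - protein - carbohydrate, normalised to a typical milk's
    ~88 g water / 100 mL): dissolved and dispersed solids displace water, so
    solute-rich milks show shallower water absorption.  Every term is affine
    in the extended regressor vector (fat, fat^2, protein, carbohydrate);
    the single curvature is the short-wave scattering saturation in fat.
    Bands whose centre lies outside the grid contribute (negligibly) through
    their Gaussian tails only; this is the analytic oracle the simulator and
    the tests share.
    """
    wavelengths = np.asarray(wavelengths, float)
    fat = table["fat_true"].to_numpy(float)[:, None]
    protein = table["protein_true"].to_numpy(float)[:, None]
    carb = table["carbohydrate_true"].to_numpy(float)[:, None]
    lactose = table["lactose"].to_numpy()
    water_fraction = (100.0 - fat - protein - carb) / 88.0

    base = config.baseline
    r = (base.shape(wavelengths)[None, :]
         * (base.a + base.b * fat + base.c * protein)
         - base.b2 * fat ** 2 * base.sat_shape(wavelengths)[None, :])
    for band in config.band_catalog:
        g = np.exp(-0.5 * ((wavelengths - band.center) / band.width) ** 2)[None, :]
        if band.component == "water":
            r = r - band.amplitude * water_fraction * g
        elif band.component == "fat":
            r = r - band.amplitude * fat * g
        elif band.component == "protein":
            r = r - band.amplitude * protein * g
        elif band.component == "carbohydrate":
            r = r - band.amplitude * carb * g
        elif band.component == "lactose":
            mask = (lactose == "present")[:, None]
            r = r - band.amplitude * carb * mask * g
        elif band.component == "lactose_free":
            mask = (lactose == "absent")[:, None]
            r = r - band.amplitude * carb * mask * g
        else:
            raise ConfigurationError(f"unknown band component {band.component!r}")
    return r


def render_replicates(table: pd.DataFrame, profile: InstrumentProfile,
                      config: SimulationConfig) -> np.ndarray:
    """Raw replicate stack (n_samples x N_REPLICATES x n_wavelengths).

    Three noise layers ride on the noise-free model:

    * per-sample scatter variability — a random gain ``1 + eps_i`` of SD
      ``scatter_sd`` on the scattering baseline term, shared by a sample's
      replicates.  It emulates globule-size, packing and repositioning
      differences between milks, which modulate the scattering level beyond
      what composition dictates; it is drawn independently per instrument
      because the two devices measure in separate sessions and geometries,
      and it is the irreducible error of purely scattering-based prediction;
    * per-replicate white detector noise of SD ``noise_sd``;
    * a per-replicate smooth correlated drift curve (white noise low-pass
      filtered along the wavelength axis) whose SD is
      ``smooth_noise_fraction`` of the white level;

    plus the instrument's constant warm-up offset.
    """
    if len(table) == 0:
        raise ConfigurationError("composition table is empty")
    wavelengths = profile.wavelengths
    clean = band_contributions(table, wavelengths, config)
    rng = np.random.default_rng([config.seed, _salt("render"), _salt(profile.name)])
    n, p = clean.shape
    if profile.scatter_sd > 0:
        base = config.baseline
        fat = table["fat_true"].to_numpy(float)[:, None]
        protein = table["protein_true"].to_numpy(float)[:, None]
        baseline_term = (base.shape(wavelengths)[None, :]
                         * (base.a + base.b * fat + base.c * protein))
        eps = rng.normal(0.0, profile.scatter_sd, size=(n, 1))
        clean = clean + eps * baseline_term
    reps = np.repeat(clean[:, None, :], N_REPLICATES, axis=1)
    if profile.noise_sd > 0:
        white = rng.normal(0.0, profile.noise_sd, size=(n, N_REPLICATES, p))
        smooth = gaussian_filter1d(
            rng.normal(0.0, 1.0, size=(n, N_REPLICATES, p)), sigma=8.0, axis=2)
        smooth *= (profile.smooth_noise_fraction * profile.noise_sd
                   / max(smooth.std(), 1e-12))
        reps = reps + white + smooth
    return reps + profile.warmup_drift


def render_spectra(table: pd.DataFrame, profile: InstrumentProfile,
                   config: SimulationConfig) -> SpectralBlock:
    """Replicate-averaged reflectance block for one instrument."""
    reps = render_replicates(table, profile, config)
    return SpectralBlock(profile.name, profile.wavelengths, reps.mean(axis=1),
                         table["sample_id"].tolist())


def simulate_dataset(config: SimulationConfig,
                     profiles: Sequence[InstrumentProfile] = (SHORTWAVE, LONGWAVE),
                     ) -> tuple[pd.DataFrame, dict[str, SpectralBlock]]:
    """Full synthetic study: compositions, label corruption, both blocks."""
    table = sample_compositions(config)
    table = perturb_labels(table, config.label_tolerance, seed=config.seed)
    blocks = {p.name: render_spectra(table, p, config) for p in profiles}
    return table, blocks


def _salt(name: str) -> int:
    return zlib.crc32(name.encode())
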