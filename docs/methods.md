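# Methods

`milknir` implements a complete chemometric calibration/validation workflow
for dual-instrument pocket NIR analysis of commercial milk, together with a
synthetic-data generator that stands in for the (undeposited) physical
measurements. This note records the models, the generator's assumptions, the
numerical choices, and what the tests do and do not establish.

## The measurement model the simulator emulates

Milk is a turbid emulsion: diffuse reflectance in the 740–2560 nm range is
dominated by scattering from fat globules (1–10 µm), with a small
contribution from protein micelles (~200 nm). Absorption features — strong
water bands and weak macronutrient overtone/combination bands — ride on top
of that scattering baseline. The generator renders, for each sample and
instrument,

```
R(λ) = g(λ)·(a + b·fat + c·protein)            scattering baseline
     − b2·fat²·s(λ)                            optional saturation (default off)
     − w(λ)·(100 − fat − protein − carb)/88    water absorption dips
     − Σ_k A_k·conc_k·G(λ; c_k, σ_k)           macronutrient bands
     + noise
```

* `g(λ)` is a gentle logistic ramp (scattering efficiency varies smoothly
  with wavelength); `b = 0.12` per g/100 mL fat dominates `c = 0.005` per
  g/100 mL protein, reflecting the fat-globule/protein-micelle asymmetry.
* Water dips sit at 970, 1450, 1950 and 2450 nm. Their depth scales with
  the water fraction: dissolved and dispersed solids displace water, so
  solute-rich milks show shallower dips. This is what couples carbohydrate
  (range 2.5–13.5 g/100 mL) to the long-wave spectrum.
* Fat bands sit at the C–H overtone/combination positions (930, 1690, 1722,
  1754, 2302, 2340 nm). Protein (918, 1020, 2055, 2180 nm) and
  carbohydrate/lactose band positions and all amplitudes are *simulator
  fiction*: plausible, freely parameterised values, not a spectroscopic
  database. Lactose-containing and lactose-free milks get distinct marker
  bands (1005/2120 vs 1040/2080 nm) scaling with carbohydrate content,
  standing in for the lactose → glucose + galactose hydrolysis signature.
* With all noise disabled, reflectance at every wavelength is an affine
  function of (fat, protein, carbohydrate) given the lactose flag — the
  closed form `band_contributions` is the analytic oracle shared by the
  simulator and the test suite. (An optional concave `b2·fat²` saturation
  term exists for studying multiple-scattering curvature; it is off by
  default.)

### Noise layers and their calibration

Three layers, chosen so the *fat calibration errors land at the scale a
pocket-NIR milk study reports* (RMSECV ≈ 0.13–0.2 g/100 mL, CV r² ≈ 0.97 at
2 latent variables):

1. **Per-sample scatter variability** (`scatter_sd`, 0.025 for both virtual
   instruments): a random gain `1 + ε_i` on the scattering baseline term,
   shared by a sample's replicates. It models globule-size, packing and
   repositioning differences between milks — the irreducible error of
   purely scattering-based prediction, not removable by replicate
   averaging. It is drawn independently per instrument because the two
   devices measure in separate sessions and geometries; this independence
   is what two-instrument fusion exploits.
2. **Per-replicate white detector noise** (`noise_sd`: 0.008 short-wave,
   0.020 long-wave — the long-wave unit is noisier), plus
3. a **smooth correlated drift** at 30 % of the white level (low-pass
   filtered noise along the wavelength axis).

Three replicates are rendered per sample and averaged before modelling.

Reference values are supermarket labels: the generator rounds true values
to one decimal and adds a uniform labelling error bounded by
`label_tolerance` (default 0.15 g/100 mL). The EU legal tolerance for fat
declarations (±1.5 g below 10 % fat) is a *maximum permitted* deviation;
declared values in practice track measured composition far more closely —
calibration errors around 0.2 g/100 mL would be impossible otherwise — so
the default is an estimate of realistic label accuracy, with the legal
bound available as a parameter.

### Composition design

45 samples; fat drawn per EU class from `class_mix` (default ¼ each of
skimmed < 0.5, semi-skimmed 1.5–1.8, whole ≥ 3.5 g/100 mL, plus "no class"
fillers spanning 0.1–3.7); protein 80 % from the typical 3–4 g/100 mL
interval with uniform tails to 1.3–7; carbohydrate 70 % from 4.5–5.5 with
tails to 2.5–13.5 (special products: sugared, high-protein, low-carb);
~20 % lactose-free, ~10 % lactose status unknown. The EU class is derived
from the true fat value; classes and lactose status are independent.

## The analysis pipeline

* **Pre-treatments.** Savitzky–Golay smoothing/derivatives
  (`scipy.signal.savgol_filter`, derivative scaled per nm, `interp` edge
  policy: the terminal window's polynomial is evaluated at the edge points,
  preserving the grid length), SNV, MSC and centring/scaling, composed in
  an ordered recipe whose learned statistics (MSC reference, column
  means/SDs) are fitted on training data only. Standard treatments:
  15-point first-order smoothing for both instruments, followed by a
  second derivative (window 15, polyorder 2 — a first-order polynomial
  cannot carry a second derivative) for the short-wave block's protein and
  qualitative work.
* **PLS1** is NIPALS with X-deflation; `b = W(P'W)⁻¹q`. Weight/loading
  signs are fixed so the largest-magnitude element is positive. PLS-DA is
  PLS1 on a 0/1 dummy with a 0.5 decision threshold. PCA is a thin SVD
  wrapper with the same sign convention.
* **Validation.** Venetian-blinds cross-validation, default "22 splits,
  5 per blind". That literal plan needs ≥110 samples; for n ≈ 45 it is
  adapted to thickness 1 (fully interleaved folds) with a logged warning.
  The LV count is the smallest whose RMSECV is within ε = 2 % of the curve
  minimum — a parsimony rule operationalising "lowest RMSECV, fewest
  factors". External validation uses the deterministic Kennard–Stone
  maximin split (ties broken by lowest index), ~2/3 training.
* **Variable selection**: VIP (mean VIP² = 1), forward iPLS (contiguous
  intervals, greedy additions while RMSECV improves by > 1 % relative;
  applied to already pre-treated data, so intervals of a derivative
  spectrum are selected, not derivatives of intervals), rPLS
  (multiplicative reweighting by |b|/max|b| until the active set is stable;
  full collapse raises), and the selectivity ratio from target projection.
* **Orthogonalization (EPO).** The interferent subspace is estimated as the
  leading principal directions of the centred spectra of samples whose
  *target* value is nearly constant while the interferent spans its range;
  all spectra are then projected onto the orthogonal complement. For
  protein with fat as interferent the package default window is protein ∈
  [3.1, 3.3] g/100 mL with 2 components; the acceptance pipeline uses
  [3.0, 3.4] with 4 components, chosen by trials on the simulator (the
  subset's scree shows the fat-driven subspace — baseline direction,
  scatter-gain, fat bands, water displacement — is more than
  2-dimensional). Window and component count are explicit parameters.
* **Figures of merit.** RMSEC/RMSECV/RMSEP; r² is the squared Pearson
  correlation between predicted and measured values (the convention is
  stated because "correlation coefficient of the regression line" is
  ambiguous). The multivariate LOD is `Δ(α, β, ν)·RMSEC·√(1 + h₀)` with
  `h₀` the mean training leverage of the k = 5 lowest-concentration
  samples and Δ = 2 for ν ≥ 25 (an exact two-quantile option exists for
  small ν). Predictions below the LOD are *flagged* detect-only, never
  censored. Systematic error is tested via the intercept CI of the
  predicted-vs-measured OLS line (df = n − 2) and, for method comparison,
  the elliptical joint (intercept, slope) confidence region from the
  two-parameter F statistic, checked against the ideal point (0, 1).
* **Exploration and fusion.** Ward or average-linkage HCA; the k = 3 cut is
  scored against the EU classes by majority-label agreement with "no class"
  samples excluded. The clustering representation is the first two PC
  scores *weighted by their variance* (not autoscaled): in the simulator
  the fat signal is concentrated in PC1 and autoscaling would inflate the
  protein/lactose-dominated PC2 to equal weight. Low-level fusion
  concatenates the pre-treated blocks and autoscales the combined matrix
  (after concatenation, so the instruments' different reflectance scales
  are equalised); mid-level fusion concatenates each block's first two PCA
  scores and autoscales those.

## What the tests show — and what they do not

The acceptance suite establishes, on the seeded synthetic study: a 2-LV fat
calibration with CV r² ≥ 0.95 on both instruments; orthogonalization
improving protein RMSECV in ≥ 90 % of 50 independent studies; perfect
cross-validated lactose discrimination on typical-carbohydrate milks;
low- and mid-level fusion within 5 % of the best single instrument in
≥ 90 % of 50 studies; perfect k = 3 fat-class recovery; and 95 % ± 1.5 %
coverage of the intercept and joint-region tests on 2000 simulated nulls.

Lactose discrimination is checked on milks with carbohydrate in the typical
4.5–5.5 g/100 mL band: the marker-band depth scales with carbohydrate, so
ultra-low-sugar lactose-free specials (2.5–3 g/100 mL) sit at the
signature's detection limit and are genuinely not separable — a property of
the physics being modelled, not a defect of the classifier.

Because band positions/amplitudes, noise magnitudes and the label-error
model are simulator choices calibrated to reproduce the *error scales* of a
real pocket-NIR milk study, passing tests demonstrate that the pipeline
recovers planted structure under realistic noise — not that any particular
real instrument will achieve these figures. Real milk spectra contain
nonlinear scattering physics, temperature sensitivity, and inter-batch
drift that the generator does not model.

## Numerical choices

* Degenerate inputs raise typed errors (`ConfigurationError`,
  `DegenerateDataError`, `ParseError`) naming the offending sample, column
  or wavelength; nothing is silently dropped. Outlier candidates
  (studentised residual > 3 or leverage > 3·LV/n) are flagged for explicit
  user action, never removed automatically.
* Rank checks use SVD with a tolerance anchored on the raw data scale;
  autoscaling treats columns with SD at rounding level as zero-variance.
* The joint-CI membership test carries an absolute slack of
  `1e−12·tr(X'X)` so numerically perfect agreement (zero residual) is
  classified as containing (0, 1).
* All randomness flows through `numpy.random.default_rng` seeded from
  `SimulationConfig.seed` plus fixed per-stage salts; the same seed gives
  bit-identical compositions and spectra.
* Problem sizes: the replicate studies in tests and the acceptance script
  use 50 independent 45-sample simulations, and coverage checks use 2000
  null replicates — sizes at which the binomial error of the reported
  rates is ~1 percentage point.
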