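# Methods

This note records the modelling assumptions, default parameters,
numerical choices and known limitations of `anthospec`. Everything here
is the package's own specification of its behaviour; defaults live in
`anthospec.config` and `anthospec.simulate.GeneratorParams`.

## 1. Quantification model

Anthocyanin content is quantified per unit leaf area from a
three-wavelength absorbance assay of a leaf extract:

- `SLW = S / W_F` — specific leaf weight, leaf area `S` (m²) over fresh
  weight `W_F` (g).
- `C_Ant = 0.08173·A537 − 0.00697·A647 − 0.002228·A663` (µmol mL⁻¹) —
  the 537 nm channel carries the anthocyanin signal; the 647/663 nm
  terms subtract chlorophyll interference.
- `Ant = C_Ant·V·M_Ant / (1000·W_F·SLW)` (mg m⁻²), extract volume `V`
  (mL), molar mass `M_Ant` = 449.2 g mol⁻¹ (cyanidin-3-glucoside).

Substituting `SLW` shows `Ant = C_Ant·V·M_Ant/(1000·S)`: fresh weight
cancels, which the test suite checks as an algebraic property.
Negative `C_Ant` (possible at very low pigment with noisy absorbances)
is kept and logged, never clipped — clipping would bias low-end
calibration samples.

**Screening.** Within each (month × groundwater-group) cell, samples
outside mean ± 3·SD are removed; the rule is iterated to a fixed point
so screening is idempotent. A Shapiro–Wilk p-value is reported per run
as a normality diagnostic, not as a gate.

## 2. Synthetic data generator

No field dataset ships with the package, so the generator is a
first-class, tested component. Its goal is *plausible difficulty*, not
botanical fidelity: enough structure that preprocessing, selection and
modelling each have real work to do.

**Concentration field.** 5 months (June–October) × 5 groundwater-depth
groups × `n_per_cell` (default 12) = 300 samples. Cell means follow a
seasonal rise-and-fall (350, 680, 760, 560, 300 mg m⁻² for months
6–10) plus a ±80 mg m⁻² per-step group offset; within-cell SD is
170 mg m⁻²; draws are clamped to the survey range [0.9, 1477.3] mg m⁻².

**Reflectance model** (325–1075 nm at 1 nm, resampled to 2.5 nm by the
pipeline). A clean spectrum is built from: a 0.10 visible baseline, a
green Gaussian bump (550 nm, σ 35), and a sigmoidal red-edge rise to a
0.64 NIR plateau whose inflection shifts from 716 nm down to 706 nm as
normalised anthocyanin increases — the planted, recoverable signal,
confined to the 685–735 nm window. Anthocyanin also brightens the blue
(465 nm Gaussian) and darkens the red (640 nm Gaussian); a chlorophyll
nuisance trough (670 nm) varies independently so red-region correlation
is partially confounded.

**Noise model**, applied per spectrum: wavelength-correlated additive
noise (SD 0.004, 5 nm correlation length), 1 % multiplicative gain
noise, and a per-spectrum additive baseline offset (SD 0.015) plus
linear tilt (SD 0.015). The baseline terms emulate illumination and
scattering drift; they are what makes derivative spectra genuinely more
informative than raw reflectance, as in real spectroscopy.

**Assay inversion.** For each sample the generator solves the
quantification equations *backwards* for absorbances that reproduce the
drawn concentration exactly (chlorophyll channels set by an
anthocyanin-dependent factor), then adds measurement noise (SD 0.01 on
each absorbance). The tabulated `Ant` is the *measured* value —
quantified from the noisy absorbances — so model validation targets
carry realistic assay error; zero-noise inversion is exact to 1e-9 and
tested.

## 3. Preprocessing

- **Resampling**: linear interpolation onto 325–1075 nm at 2.5 nm
  (301 bands); the target grid must lie inside the measured support (no
  extrapolation).
- **Smoothing**: Savitzky–Golay, window 11 points (27.5 nm), polynomial
  order 3. The filter can undershoot near zero-clipped dark bands;
  values within ±0.02 of [0, 1] are nudged back in, larger violations
  are an error.
- **Derivatives**: Savitzky–Golay first/second derivatives with respect
  to wavelength (per nm), computed only from smoothed spectra — the
  container's `kind` field enforces raw → smoothed → fd/sd ordering.
- **Correlation curves**: per-band Pearson r against concentration with
  two-sided p-values and a Bonferroni-adjusted column.

## 4. PLS engine and RMSECV

All selectors share one scorer: K-fold (default 5) RMSECV of a PLS1
(univariate NIPALS) model, minimised over 1–10 components. One NIPALS
pass yields the coefficient path for every component count, so a full
CV sweep costs K fits. Predictors are autoscaled on the training fold;
folds are a seeded permutation split into near-equal blocks; RMSECV
ties prefer fewer components. The engine is cross-checked against
scikit-learn's `PLSRegression` to ~1e-8 and reduces to OLS at full rank.

## 5. Wavelength selection

- **CARS** (50 Monte-Carlo runs, 80 % calibration subsets): bands are
  weighted by normalised |PLS coefficient|; an exponential retention
  schedule `r_i = a·e^(−k·i)` (all bands at run 1, exactly 2 at run N)
  truncates, then weighted sampling with replacement keeps the union;
  the minimum-RMSECV iteration's subset wins.
- **SFLA** (50 frogs, 5 memeplexes, cardinality 15, 5 local steps × 20
  global iterations): fitness −RMSECV; ranked round-robin memeplex
  partition; the worst frog leaps toward the local best, then the
  global best, else restarts (the incumbent best is protected).
  Final band probabilities are fitness-rank-weighted membership
  frequencies; a nested backward sweep over that ranking returns the
  minimum-RMSECV prefix.
- **RFECV** (step 1, min 2 bands): backward elimination of the smallest
  |autoscaled PLS coefficient|, RMSECV recorded at every size.

All selectors are deterministic per seed, break weight ties toward the
lower wavelength, and return a `SelectionResult` with the RMSECV trace.

## 6. Vegetation indices

Four families (ARI, CI, DVI, NARI) over *ordered* pairs of the selected
bands — CI is not antisymmetric, so orientation matters and both
orientations compete in the ranking. Because derivative values cross
zero, every reciprocal/ratio is masked where |denominator| < 1e-8;
pairs with more than 20 % masked samples are dropped from ranking, and
residual masked entries in retained pairs are imputed with the column
median (counts recorded per column). The top-10 pairs per family by
|Pearson r| against concentration form the 40-column modelling matrix.

## 7. Modelling and evaluation

- **Split**: concentrations are binned into 5 equal-width strata, each
  split 7:3 with largest-remainder rounding so the global calibration
  count is exactly `round(0.7·n)`; empty strata merge into neighbours
  with a warning.
- **SVM**: RBF SVR, grid C ∈ 2^(−1..9), γ ∈ 2^(−7..3), ε ∈ {0.01, 0.1,
  0.5}×SD(y), chosen by 5-fold RMSE with per-fold standardisation of X
  and y (no leakage from validation folds into scalers).
- **1-D CNN** (pure numpy): conv(16, k3) → ReLU → conv(32, k3) → ReLU →
  global average pooling → dense(32) → ReLU → dense(1); Adam (lr 1e-3),
  batch 16, ≤ 500 epochs, early stopping on an inner 20 % split
  (patience 50, best weights restored). All randomness flows from one
  seed, so training is bit-reproducible.
- **Metrics**: R² (sum-of-squares form), RMSE (mg m⁻²), RPD =
  SD(ddof = 1)/RMSE with the bands ≥ 1.4 usable, 1.8–2 good, ≥ 2 very
  good. The standard grid is {FD, SD} × {CARS, SFLA, RFECV} × {SVM,
  1D-CNN} = 12 models; "best" is highest validation R², ties broken by
  higher RPD then lower RMSE.

## 8. Numerical and reproducibility choices

- CSV round-trips use `%.17g` formatting and pandas
  `float_precision="round_trip"` parsing, so write→read is bit-exact.
- Stage seeds spawn from the master seed via
  `numpy.random.SeedSequence`, so stages are independently re-runnable;
  the run manifest records config hash, stage seeds, SHA-256 file
  digests and timings.
- Ties anywhere (component counts, band weights, grid points, strata)
  break deterministically, documented at each site.

## 9. Limitations

- The generator is a caricature: no canopy BRDF, water-band physics,
  instrument response, or between-leaf structural variation; absolute
  performance numbers on synthetic data (R² ≈ 0.95) say the pipeline
  recovers *planted* signal, not how it would score on field spectra.
- PLS1 only (single response); no multi-trait extension.
- The CNN is sized for ~40-feature index vectors and a few hundred
  samples; it is not a general-purpose spectral deep-learning model.
- Equal-width strata can merge under strongly skewed concentration
  distributions, reducing the effective stratification.
- SVM grid search is exhaustive and single-threaded; on much larger
  datasets it becomes the dominant cost.
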