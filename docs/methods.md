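# Methods

`grapespec` implements an in-situ VNIR–SWIR point-spectroscopy workflow for
predicting the sugar content of wine grapes (°Brix, total soluble solids) from
contact-probe reflectance spectra on the 350–2500 nm range.  This note
documents the models, the numerical choices, what the synthetic generator does
and does not emulate, and the problem sizes used by the test suite and the
benchmark script.

## Data model and downsampling

A spectral library couples, per sample, a reflectance spectrum R(λ) on a
shared wavelength grid with a refractometric ground truth y (°Brix, plausible
window 0–32, the instrument scale) and metadata (variety, year, bunch label).
The instrument grid is 350–2500 nm at 1 nm (2151 points), but the true optical
resolution (FWHM) of field spectroradiometers is several nm, so modelling uses
a 10 nm grid: {350 + 10k | k = 0..215}, 216 bands.

Downsampling takes the **mean over a centered half-open window**
[λ − step/2, λ + step/2), truncated at the range edges.  Window averaging (as
opposed to plain decimation, which is available as an option) suppresses
detector noise, consistent with the coarser true FWHM that motivates
downsampling in the first place.  The operator is idempotent on a grid already
at the target step and never touches y or metadata.

Quartiles (library summaries and the RPIQ metric) use linear interpolation
between order statistics — numpy's default percentile rule, the common
spreadsheet convention.  The sample standard deviation (ddof 1) is used
throughout; a single-record group reports std 0.

## Pre-treatments: the nine spectral inputs

Eight per-spectrum transforms compose into nine named inputs:
`Ref`, `Ref+SNV`, `Ref+SG1`, `Abs`, `Abs+SNV`, `Abs+SG1`, `Abs+SG1+SNV`,
`Abs+SG2+SNV`, `CR`.

* **SNV** (standard normal variate): per-spectrum centering and scaling to
  unit *sample* (ddof 1) standard deviation.  A constant spectrum is rejected
  (zero variance).
* **Abs** (pseudo-absorbance): A = −log10(R), motivated by the empirical
  Beer–Lambert law.  Reflectance below 1e−4 is clamped to 1e−4 (and logged)
  rather than rejected: field spectra can contain non-positive noise
  excursions and a hard error would discard whole libraries.
* **SG1 / SG2** (Savitzky–Golay derivatives): windowed local least-squares
  polynomial fit, window 5, polynomial order 3, first or second derivative.
  Derivatives are scaled **per nm** (scipy's `delta`), making them invariant
  to the grid step.  Edge policy: the polynomial of the nearest full window is
  evaluated at the edge positions (scipy `mode="interp"`), keeping output
  length equal to input length — required because all nine inputs must share
  one feature grid.
* **CR** (continuum removal): division by the upper convex hull of
  (λ, R) computed with a monotone-chain sweep.  Collinear points are retained
  as hull vertices, so a point lying exactly on the chord between neighbours
  maps to exactly 1.  CR is applied to reflectance (not absorbance).

All nine transforms are per-spectrum (no cross-sample statistics), so applying
them before cross-validation splitting leaks nothing.  Downsampling always
precedes pre-treatment.

## Model families and search spaces

Four regressors sit behind one fit/predict contract:

* **PLS** — latent variables searched in [1, 100], capped at
  min(n_features, n_train − 1) at fit time (the cap is recorded).
* **RF** — trees {50, 100, 150, 200} × max-features {"max", "sqrt", "log2"},
  where "max" means all features.
* **SVR** (RBF) — ε ∈ {0.01, 0.025, 0.05, 0.075, 0.10, 0.15, 0.20} ×
  C ∈ {2⁻², …, 2⁹}.  The kernel width γ uses the "scale" heuristic and is
  recorded with the fit; only ε and C are searched.
* **CNN** — a 1-D convolutional network implemented in NumPy: 1–3
  convolutional blocks (8–32 filters, kernel 3/5/7, optional batch
  normalization, optional max pooling with window 2), flatten, 1–3 fully
  connected ReLU layers (8–64 units, L2 penalty 4e−4 on their weights), one
  linear output.  Valid (unpadded) convolutions; ReLU hidden activations;
  mean-squared-error loss; Adam with log-sampled learning rate in
  [1e−4, 1e−2]; batch size ∈ {4, 6, 8}; step decay halving the learning rate
  every 60 epochs; at most 200 epochs; early stopping on validation loss with
  patience 40, restoring the best weights.  Input standardization (none /
  per-band min-max to [−1, 1] / standard score) is itself a hyperparameter;
  its statistics, like the internal standardization of the target, come from
  the training partition only.  Training runs in float32; a fit is
  bit-reproducible given (data, config, seed).

Inputs to PLS and SVR are standardized inside the fitted pipeline (statistics
from the training folds only); without this, a single C/ε or latent-variable
grid could not serve pre-treatments whose scales differ by orders of
magnitude.

Grid enumeration order is deterministic (sorted by parameter name, then
value), so "first minimum" tie-breaking is reproducible.

## Nested cross-validation and selection

The outer loop is a seeded 5-fold partition (uniform shuffle; optional
y-quintile stratification exists but is off by default).  Within each
calibration set, an inner 5-fold loop scores every grid point; the point
minimizing the **mean internal-validation RMSE** is refit on the full
calibration set and evaluated once on the held-out outer fold.  R² and RPIQ
are reported but never used for selection.  One fixed inner partition is
shared by all grid points of an outer fold (cheaper and lower-variance than
re-randomizing per point).  An audit trail records, per outer fold, the test
indices and every index visible to the inner loop; tests assert their
intersection is empty.

For the CNN the inner loop drives **Hyperband-style successive halving**: n
configurations are sampled from the search space; rung r trains every
survivor to a cumulative epoch budget max_epochs / η^(rungs−1−r) (η = 3 by
default), scores it by mean inner-fold validation RMSE, and keeps the top
⌈n/η⌉; the final rung trains one configuration at the full 200 epochs.
Survivors **resume** training from their rung checkpoint (optimizer state,
learning-rate schedule and early-stopping bookkeeping carry over) rather than
restarting, which is both the textbook resource-allocation scheme and roughly
a quarter cheaper.  A configuration whose pooled feature length collapses
below the kernel size is scored infeasible.  The winner is refit on the whole
calibration set; because the early-stopping rule needs a validation set, a
seeded 20 % split of the calibration set is carved out for monitoring during
this refit.

PLS latent-variable counts above the fit-time cap all collapse onto the same
capped model; the inner loop scores each distinct effective point once.

## Metrics

With ŷ the prediction, ȳ the observed mean, N the fold size:

    R²   = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²
    RMSE = sqrt( Σ(yᵢ − ŷᵢ)² / N )          [°Brix]
    RPIQ = (Q3 − Q1) / RMSE

Per-fold RPIQ uses the **fold's own** observed quartiles, which is why a
fold-mean RPIQ generally differs from (global IQR)/(mean RMSE); the global
variant is also exported.  RPIQ is undefined for a perfect fit (RMSE 0) and
raises; R² is undefined for constant observed values and raises.

## Wavelength importance

* **Mutual information** (pre-hoc, per band vs y): k-nearest-neighbour
  estimator with k = 3, seeded; constant bands are reported as 0 and flagged.
* **VIP** (PLS): VIP_j = sqrt( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ) with
  SS_a = q_a² t_aᵀt_a; mean squared VIP is 1 by construction.
* **Gini** (RF): normalized total variance-reduction per feature; sums to 1.
* **SAGE** (any model, used for SVR and CNN): permutation-sampling Shapley
  estimate of each band's contribution to expected squared-error-loss
  reduction, marginalizing unrevealed bands by imputation from a background
  sample (≤128 rows from the training fold).  Defaults: 256 permutations for
  production profiles (the orchestrator uses a smaller, configurable budget);
  Monte-Carlo standard errors and an efficiency diagnostic (Σ scores −
  [baseline loss − full-model loss], exactly 0 by telescoping for this
  estimator) are attached.  Contiguous-band grouping is deliberately not the
  default, matching per-wavelength profiles.

Profiles are computed per outer fold on the same pre-treated spectra the
model consumed and fold-averaged (both mean scores and mean ranks are
exported).  Caveat: derivative pre-treatments shift apparent peaks slightly
off the true absorption band (a first derivative is zero at the band center
and extremal on its flanks).

## Synthetic generator

Because field grape libraries are generally not deposited, the generator
produces libraries carrying the structure the pipeline assumes:

    R(λ) = baseline(λ) · exp(−Σ_k depth_k · G(λ; c_k, w_k)) · (1 + m₀ + m₁·t(λ)) + a₀ + noise(λ)
    depth_k = (base_k + coupling_k · brix) · (1 + jitter_k)

* Baseline: sigmoidal visible edge plus a gentle SWIR tilt; the red variety
  (Syrah) preset shifts the edge toward 700 nm, darkening 450–700 nm relative
  to the white varieties.
* Fixed pigment/water bands at 680, 970, 1200, 1440, 1920 nm, so mean
  absorbance shows the canonical dips.
* Sugar-coupled bands at 680, 730, 920, 960, 1150 nm — depth linear in °Brix.
  Couplings are calibrated so ordinary least squares on *noiseless*
  pseudo-absorbance spectra reaches about R² = 0.95; this signal ceiling, plus
  default measurement noise, puts the best attainable model accuracy in the
  same regime as published field studies of grape TSS.  The couplings are
  statistical stand-ins, not estimates of grape chemistry.
* Per-sample multiplicative/additive scatter (sd 0.03 / 0.015 / 0.008 for
  the flat multiplier, wavelength-linear multiplier and additive offset) and
  heteroscedastic noise per detector region (sd 0.002 / 0.004 / 0.006
  reflectance units for 350–1000 / 1000–1910 / 1910–2500 nm, echoing the
  three-detector construction of field spectroradiometers).
* °Brix: truncated normal per variety; default moments (mean, sd, min, max)
  follow the published per-variety field statistics, e.g. Syrah
  17.22 ± 5.04 on [4.9, 30.0]; everything lies within the global field range
  [4.2, 31.4].
* Depth jitter (sd 0.11 on sugar bands, 0.05 on fixed bands) is the
  °Brix-independent variance component that caps attainable R².

What it does **not** emulate: radiative transfer in the berry (skin/pulp
scattering), temperature and water-status effects, instrument drift between
calibrations, correlated °Brix structure within a bunch, or year/phenology
effects (year is sampled independently of °Brix).  Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it assumes —
not that any accuracy level transfers to real vineyards.

## Problem sizes and budgets

The package's benchmark (`scripts/acceptance.py`, also exercised by the test
suite) uses a single-variety Syrah-like library of n = 240 on the 216-band
grid, the `Ref+SG1` input, nested 5-fold CV, and a reduced Hyperband budget of
8 sampled configurations (η = 3; rungs at 22/67/200 cumulative epochs) — a
deliberately desk-scale configuration that one CPU completes in minutes while
preserving the full nested structure.  Unit tests use 20–600-sample libraries
and narrowed (but in-range) CNN spaces where a full search would add nothing
to the property being checked.

## Known limitations

* The CNN is a compact NumPy implementation: single-threaded, CPU-only, and
  sized for hundreds of samples × hundreds of bands, not for large designs.
* SAGE on 216 bands is Monte-Carlo; with small permutation budgets the
  per-band standard errors are material and are reported for that reason.
* `select_best` keys on mean internal-validation RMSE; with few samples this
  estimate is itself noisy, and ties are broken toward simpler chains.
* Pooling across years is the default (year is recorded for optional
  stratification); nothing in the synthetic generator distinguishes years.
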