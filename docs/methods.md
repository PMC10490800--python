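# Methods

## Problem and model

The quantity of interest is the moisture content of pelletized feed,
defined gravimetrically as `H = 100·(M1 − M2)/M1` (percent by mass, wet
basis). The estimator is a linear calibration between H and the pellet's
mean near-infrared reflectance spectrum: water's O–H overtone/combination
bands near 1450 nm and 1940 nm deepen proportionally with H, so after
suitable preprocessing a partial-least-squares regression on a subset of
informative wavelengths predicts H from reflectance alone. The model is
then applied per pixel to chart the spatial moisture distribution.

The chain is: reflectance calibration → segmentation → mean spectrum →
edge-band trim → MCCV outlier rejection → preprocessing → wavelength
selection → regression → evaluation → mapping. Stage order is fixed
(outlier rejection on trimmed raw spectra, before preprocessing; selection
after preprocessing); `run_pipeline` exposes a flag-free declarative
config for the whole sequence.

## Key conventions and parameters

**Grid.** 256 channels linearly spanning 935.5–2539 nm (≈6.29 nm
sampling). Edge trimming keeps the closed interval [960, 2489] nm, which
on this grid is exactly 244 bands. Band indices are 0-based internally.

**Reflectance correction.** `I = (I0 − IB)/(IW − IB)` elementwise. Pixels
with any band where `IW − IB ≤ 0` are excluded from the valid mask rather
than clamped — silently clamped pixels would bias every downstream
statistic. A common positive gain on all three frames cancels exactly.

**Segmentation.** Otsu two-class threshold on the band-averaged
reflectance, bright class by default, followed by removal of connected
components below a configurable pixel count (default 20). Any criterion
that reproduces the mean-spectrum contract is acceptable; this one is
automatic and parameter-light.

**Preprocessing.** FD/SD are plain finite differences scaled by the
channel spacing (`Δλ`, `Δλ²`); SG is the separate Savitzky–Golay smoothed
derivative (window 9, fitted polynomial degree 3 — the degree is not
prescribed anywhere, so it is configurable — derivative order 2).
Derivative outputs shrink (FD: p−1 channels at interval midpoints, SD:
p−2, SG: p−8 at window centers) instead of padding: fabricated edge values
would otherwise enter variable selection. MSC/MC/MMN statistics are fitted
on the calibration split only and reused everywhere (test set, pixels), so
no information leaks across the split; MMN is per-band, and out-of-range
test values are documented rather than clipped. Constant rows fail SNV/MSC
at tolerance 1e−12 (per-row error; during mapping the pixel is marked
missing and counted instead of aborting).

**MCCV outlier rejection.** 1000 cycles of random 75% calibration / 25%
held-out PLS fits; the PLS component count is chosen once on the full data
(10-fold CV, cap 15) and held fixed — per-cycle tuning would cost 1000×
more and changes nothing qualitatively. Per sample we accumulate held-out
residual MEAN and STD (ddof 1). The rejection cutoff is deliberately
scale-free: robust z (median/MAD, consistency factor 1.4826) above 3 on
|MEAN| or on the high side of STD; MAD = 0 falls back to a classical
z-score with a warning. The threshold is a declared stand-in — the
underlying study motivating this workflow names rejected samples but not
its cutoff. Rows are canonicalized by sample ID before drawing subsets, so
the report is invariant to input order.

**CARS.** N = 40 Monte Carlo runs, 80% sample draws (the per-run fraction
is unstated in the source procedure; 0.80 is the community default),
10-fold RMSECV scoring with folds fixed across runs. The retention ratio
follows the exponentially decreasing function `r_i = μe^{−ki}` with
`μ = (n/2)^{1/(N−1)}`, `k = ln(n/2)/(N−1)`, read with n = number of
wavelengths (giving r₁ = 1, r_N = 2/n, the canonical schedule). Each run
fits PLS on the surviving wavelengths, ranks them by normalized absolute
coefficients, and keeps the top ⌈r_i·n⌉. The *adaptive reweighted
sampling* step (weighted bootstrap whose unique draws survive) is
implemented but **off by default**: its unique-of-draws survival rule
multiplies the retained count by ≈0.63 per run regardless of the EDF
schedule, collapsing the variable set within ~10 runs and forcing the
RMSECV argmin to the earliest runs. EDF-only elimination reproduces the
canonical two-stage trace (fast coarse elimination, slow fine selection,
mid-schedule minimum). Ties in the trace resolve to the earlier run.

**SPA.** Columns are mean-centered; each step replaces remaining columns
by their component orthogonal to the last selected column and takes the
largest residual norm. Chains over all start columns and lengths are
scored by cross-validated PLS RMSE (not the classical MLR validation-set
variant, to keep both selectors comparable); ties prefer the shorter
chain, then the lower start index, with a 1e−9 relative tolerance so
floating-point dust cannot override the tie-break. Scanning all starts is
O(p²) in CV fits; `starts` can restrict the scan for wide matrices.

**Regression.** PLSR delegates to scikit-learn's NIPALS implementation
(no scaling; centering internal). The fitted model is also flattened to
`(b0, b)`; factorization and flat predictions agree to 1e−8, and at full
rank PLSR reproduces ordinary least squares (both are tested against a
normal-equations oracle). Component count: 10-fold CV scan 1..15 (rank
capped), argmin with ties to the smaller count. RFR uses bootstrapped CART
trees, a third of the features per split (the regression-forest custom),
mean aggregation, defaults 100 trees / minimum leaf 5, grid-tunable over
trees {100..1000} × leaf {1..10}. The train/test split is random 75/25 by
default (matching the MCCV convention); Kennard–Stone is available.

**Metrics.** R² = 1 − SS_res/SS_tot and RMSE per role (calibration,
cross-validation, prediction); RPD = sd_{n−1}(y_test)/RMSEP; SE is the
bias-corrected standard error of prediction, i.e. the ddof-1 standard
deviation of the test residuals. SEL from duplicate determinations uses
the duplicate-analysis convention `SEL = sqrt(Σd_i²/(2m))`, which
converges to the single-measurement sd of the reference method. RMSECV
reported after wavelength selection is computed on the calibration set
whose data also drove the selection, so it is optimistic relative to
RMSEP — the prediction-set numbers are the honest yardstick.

**Mapping.** Per masked pixel: trim → apply the training-fitted
preprocessing → restrict to the selected indices (which live on the
preprocessed grid, so derivative shrinkage is already accounted for) →
predict. No spatial smoothing. For a purely linear chain (trim, FD/SD/SG,
MC, linear model) the map mean equals the prediction from the mean
spectrum exactly; SNV/MSC break this only through pixel-level
nonlinearity. Display clipping and the 1st/99th-percentile default color
range affect rendering only, never the stored values.

## The synthetic generator

`generate_spectra` builds each sample as

```
x_i(λ) = g_i · [ base(λ) + drift_i(λ) − H_i·water(λ) − nuisance_i(λ) ] + o_i + ε_i(λ)
```

* `water(λ)`: Gaussians at 1450 nm (σ 45 nm) and 1940 nm (σ 55 nm) with
  depths 0.020 and 0.027 reflectance per percentage point of moisture —
  the 1940 nm combination band is the stronger one; at the wettest
  samples (~16%) reflectance at 1940 nm drops to ≈0.2, strong but not
  saturated. The noiseless, scatter-free construction is exactly affine
  in H, and the generator records dX/dH as ground truth.
* `base(λ)`: a bright, gently sloping matrix spectrum with **fixed**
  dry-matter absorption bands (2100 and 2350 nm, σ 30 nm — the
  carbohydrate/cellulose region). These do not vary between samples; their
  curvature is what lets a derivative-domain model read off the scatter
  gain and deconfound it.
* `nuisance_i(λ)`: protein/fat/fibre-like bands at 1100, 1720, 2300 nm
  whose concentrations vary with 8% rsd between samples.
* `g_i ~ N(1, 0.05)`, `o_i ~ N(0, 0.02)`: per-sample multiplicative
  scatter and additive offset — exactly the distortions MSC/SNV are
  designed to remove; `drift_i`: low-order Chebyshev baseline wobble.
* `ε_i(λ)`: channel noise with total sd 0.002 reflectance. Because these
  spectra are *means over thousands of pellet pixels*, iid detector noise
  averages down to ~1e−4; the budget is therefore dominated by a
  wavelength-smooth presentation/illumination component (Gaussian
  correlation length 4 channels) over a white floor of 1.5e−4. An iid
  white model at the full 0.002 would be physically wrong for mean
  spectra and would make any derivative-domain calibration impossible at
  these sample sizes (even ridge regression caps below R² ≈ 0.4 there —
  the second difference amplifies white noise ~60× relative to the broad
  water-band curvature).

`generate_scene` places one elliptical pellet on a dark tray, gives it the
first sample's spectrum plus a smooth low-frequency moisture field
(sd 0.3 percentage points, so maps show structure without breaking the
sample-level truth), converts reflectance to detector counts through
spatially varying dark/white frames, and records the pellet mask and the
per-pixel moisture field. `generate_sparse_dataset` is a deliberately
abstract benchmark (iid Gaussian design, a handful of truly informative
columns) for variable-selection and outlier studies where the question is
combinatorial rather than spectroscopic.

What the generator does **not** emulate: temperature and path-length
effects, pellet 3-D geometry and shadowing, detector nonlinearity, smile/
keystone distortions, and any particular camera's radiometry. Passing
tests on synthetic data therefore demonstrate that the algorithms are
implemented correctly and behave as designed under the stated noise
model — not that a real instrument will reach the same figures.

## Numerical choices

* Seeds: one integer drives every stochastic stage; fixed seed ⇒
  bit-identical outputs (tested). Fold assignments use seeded k-fold
  shuffles and are reused across comparisons.
* Uniform-grid tolerance: derivative operators accept ≤2% spacing
  deviation, so grids round-tripped through the 0.1 nm CSV headers remain
  usable; programmatic grids are uniform to 1e−9 nm.
* Constant-row tolerance 1e−12 (SNV sd, MSC slope); SPA rank-exhaustion
  tolerance 1e−12 with warned truncation; CARS keeps ≥2 variables and
  caps the PLS component count by the surviving variable count (warned).
* ENVI I/O: plain-text header with a mandatory wavelength list, float32
  binary, BIL default, BIL/BIP/BSQ on read; header/binary size mismatches
  are hard errors.
* Empty segmentation masks, contrast-free images, degenerate white≤dark
  references, mass-gain inputs to the moisture formula, and zero-variance
  references in R²/RPD all raise (or report NaN where the metric is
  genuinely undefined) rather than returning silently wrong numbers.

## Limitations

* The MCCV rejection threshold and the SEL duplicate convention are
  declared stand-ins; the source procedure names neither.
* Wavelength selection is evaluated by CV on the same calibration data
  that drives it; RMSECV after selection is optimistic (see above).
* SPA's full start-column scan is quadratic and intended for the
  few-hundred-band regime; restrict `starts` beyond that.
* At 3% contamination the single-pass MCCV rule sits near its detection
  boundary for +8-point reference errors: contaminated training subsets
  absorb part of the shift, and an occasional planted outlier lands just
  under z = 3. Iterated rejection would be more powerful but is out of
  scope.
* The pipeline evaluates one preprocessing/selector/model combination per
  run; sweeping combinations is a loop over configs, not a built-in.
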