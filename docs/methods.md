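# Methods

This note documents the models, parameters and design choices behind
`ramanid`, and what its synthetic benchmark does and does not establish.

## Spectral preprocessing

Every single-cell spectrum passes through a fixed chain:
crop → baseline correction → smoothing → max-normalization.

**Baseline (ModPoly).**  Raman spectra of biological cells sit on a broad
fluorescence background.  We estimate it by iterative modified polynomial
fitting: fit a polynomial to the spectrum, clamp the spectrum to the fit
wherever it exceeds the fit, refit, and repeat until the fitted curve
changes by less than `baseline_tol` (relative to the spectrum scale) or
`baseline_max_iter` is reached.  Clamping from above makes the polynomial
hug the background rather than the peaks.  Defaults: order 5 (flexible
enough for fluorescence curvature over a 1200 cm⁻¹ window without eating
8 cm⁻¹-wide bands), `max_iter` 100, `tol` 1e-3.  The fit uses a Chebyshev
basis on [−1, 1]; at order 5 a raw power-basis Vandermonde is already
poorly conditioned.  Because clamping only modifies the response vector,
the design pseudo-inverse is computed once and each iteration is a matrix
product, so whole spectrum sets are corrected vectorised.

**Smoothing.**  Savitzky–Golay with window 11 points and polynomial
order 3 — common Raman practice: the window is shorter than the ~19-point
FWHM of an 8 cm⁻¹ band on a 1 cm⁻¹ grid, so band shapes survive while
pixel noise is attenuated.

**Normalization.**  Negative residuals left by baseline subtraction are
clipped to zero, then each spectrum is divided by its maximum.  Clipping
first is what makes the advertised [0, 1] range an invariant; division
alone does not bound the minimum.  A spectrum that is entirely ≤ 0 after
correction raises an error rather than producing NaNs.

## Characteristic peaks and significance tiers

Peaks are local maxima of a group mean spectrum with prominence at least
`min_prominence` (default 0.05) of the spectrum maximum.  Per-cell band
intensity is the windowed maximum within ±5 cm⁻¹ of the peak position —
robust to ±1–2 cm⁻¹ grid shifts, unlike reading a single pixel; fitted band
areas are out of scope.  Between-species differences are tested per band
with Kruskal–Wallis (multiclass, no normality assumption; one-way ANOVA is
available as an option) and encoded as tiers: 0 (p > 0.05), 1
(0.01 < p ≤ 0.05), 2 (0.001 < p ≤ 0.01), 3 (0.0001 < p ≤ 0.001), 4
(p ≤ 0.0001); boundaries are inclusive on the significant side.  Tiers are
reported on raw p-values, the convention for this kind of per-band
annotation; Benjamini–Hochberg correction across bands is available but off
by default.  2-D cluster visualisation delegates to scikit-learn's t-SNE
with a fixed seed.

## Base classifiers

Eight learners sit behind one contract — `predict_proba` returns a
row-stochastic matrix over a shared, sorted class order and `predict` is
its argmax (ties to the earlier class):

* **LDA** — scikit-learn, library defaults.
* **SVM** — linear kernel, C = 1; probabilities by Platt-style sigmoid
  calibration (5-fold, single calibrated model).
* **RF** — 100 trees.
* **XGBoost** — 60 rounds, depth 4, histogram method, single thread.
* **KNN** — k = 5; probabilities are neighbour vote fractions.
* **PLS-DA** — authored here: one-hot class indicators, PLS2 regression of
  the indicator matrix on the spectra (scikit-learn's PLSRegression core,
  10 components by default, capped at n−1), softmax over predicted
  responses for probabilities, argmax for the class.
* **CNN** — a compact NumPy 1-D convolutional network (manual
  backpropagation, Adam 3e-3, 30 epochs, batch 32): mean-pool downsample ×4
  → conv(9, 8 filters) → ReLU → max-pool(4) → conv(5, 16 filters) → ReLU →
  flatten → dense softmax.  The flatten head keeps band *position*, which
  carries the signal when all species share peak positions and differ only
  in amplitude pattern.
* **LSTM** — a compact NumPy LSTM: the spectrum is cut into 30 contiguous
  chunks read as a sequence, single layer of 64 hidden units, final hidden
  state → dense softmax; same optimiser schedule.

Two numerical choices matter for the deep models on spectra.  Inputs are
centred per feature but scaled by one global standard deviation —
per-feature scaling would amplify the near-pure noise in flat spectral
regions to unit variance and invite memorisation.  Training adds Gaussian
jitter (sd 0.1 in standardised units) to each minibatch; with ~10³ training
cells this augmentation is the difference between ~82% and ~89% held-out
accuracy at matched training accuracy.  Both nets are deterministic given
their seed.

## Ensemble meta-classifier

Given the fitted bank and one accuracy per model, the combiner (i) keeps
the top K = 5 models by accuracy, ties broken by a fixed registry order;
(ii) weights each kept model by its normalized accuracy
w_n = acc_n / Σ acc (computed over the *selected* members, i.e.
renormalized after selection — the natural reading of a weights-sum-to-one
fusion); (iii) fuses probabilities P = Σ w_n P_n(X), a convex combination
of row-stochastic matrices and hence row-stochastic without renormalization;
(iv) predicts the argmax class, ties to the earlier class label.

The accuracies that become weights are measured on an internal validation
split (default 20%) of the training data, so the ensemble never sees
held-out labels.  Weighting by test-set accuracy — a protocol some studies
describe — is reproducible by passing the test data explicitly
(`accuracy_data=`), at the documented price of leakage.

## Evaluation protocol

* Stratified 70/30 split: per class, floor(0.7·n) cells to training (an
  epsilon guards the floor against float error: 0.7 × 180 is 125.999… in
  binary), seeded shuffle, disjoint and exhaustive.
* Repeated stratified k-fold CV (defaults 10 × 10 = 100 resamples): each
  repeat is reseeded deterministically; inside every fold the full suite is
  refitted and the ensemble rebuilt from training-fold data only.  The
  report carries per-resample records, median/quartile summaries (the
  box-plot statistics), and the ensemble's pooled confusion matrix.
* Metrics from a confusion matrix: accuracy; macro one-vs-rest sensitivity
  and specificity (averaged over classes where the rate is defined — a
  class with no true cells contributes no sensitivity term, rather than a
  fake zero); Cohen's kappa (p₀ − p_e)/(1 − p_e).  When p_e = 1 (all mass
  in one row-column cell) kappa is defined as 1 if the matrix is perfect
  and 0 otherwise.  Margins of empty confusion rows/columns are reported as
  NaN, never as 0%.

## Synthetic Ramanome generator

The generator is the package's test bed and default benchmark.  Each cell
spectrum is a sum of Gaussian bands at the nine characteristic positions
(805, 851, 1000, 1095, 1240, 1328, 1450, 1570, 1653 cm⁻¹; σ = 8 cm⁻¹)
with a species-specific amplitude vector, times a per-cell per-band
lognormal jitter (CV 0.08, cell-to-cell metabolic variability) and a
per-replicate lognormal shift (sd 0.03, culture batch effects), plus an
order-3 polynomial fluorescence drift with per-cell coefficient jitter
(mean coefficients (0.8, 0.4, −0.3, 0.2) on x∈[0,1], 25% relative sd — so
the baseline stage has real work to do) and white noise (sd 0.02; band
amplitudes are O(1)).  The default design is 9 species × 3 replicates ×
60 cells = 1,620 cells on a 600–1800 cm⁻¹, 1 cm⁻¹ grid.

The nine amplitude vectors are constructed, not measured.  They encode the
qualitative class structure such a study reports: one five-member cluster
and one pair of nearly collinear profiles (within-group cosine ≈ 0.99,
standing in for subspecies that overlap in a 2-D embedding) plus two
well-separated species.  Band perturbations of ±0.05–0.10 set the
difficulty so that per-class recall stays high while the residual
confusion falls inside those groups.

What the generator does **not** emulate: cosmic-ray spikes, wavenumber
miscalibration between cells, peak-position or width shifts, non-Gaussian
band shapes, heteroscedastic shot noise, instrument response functions, or
any real biochemical covariance between bands.  Passing tests on this
benchmark therefore demonstrate that the pipeline's machinery is correct
and well-calibrated under its stated noise model — not that the reported
accuracy transfers to any particular instrument or organism panel.

## Problem sizes used by the test suite and acceptance script

The full published-style protocol (10 × 10-fold CV over all eight models)
is hours of CPU; the package's own checks use reduced but honest versions:
the benchmark cross-validation test runs 1 repeat × 3 stratified folds of
the full 1,620-cell default set with all eight models; the ensemble-vs-best-
member tendency test runs 10 generator seeds on a 3-species × 24-cell
benchmark with the classical bank; `scripts/acceptance.py` uses a single
stratified 70/30 split of the default set with all eight models.  All
thresholds (ensemble CV accuracy > 90%, every per-class TPR > 80%, ensemble
within 1 point of its best member) are asserted at these sizes.

## Known limitations

* The deep models are intentionally small CPU implementations; they match
  the classical models on the synthetic benchmark but are not tuned for
  real spectral corpora, and their training (unlike their prediction) is
  the pipeline's main cost.
* PLS-DA probabilities come from a softmax over regression responses; they
  are monotone in the responses but not calibrated.
* The significance tiers test each band marginally; correlated bands are
  not modelled.
* Instrument-native file formats (SPC, JCAMP-DX) are out of scope; spectra
  enter as delimited text.
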