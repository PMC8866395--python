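# Methods

This document records what the package computes, the parameter choices and
why they were made, and where the approach is known to be limited.

## 1. Synthetic cohort generator

Each subject gets a diagnosis (case/control at a configurable prevalence,
default 0.5), a sex (configurable ratio), a site assignment (3 sites by
default, cyclically balanced within strata), a BOLD-like time series
(`n_timepoints x n_rois`), an anatomical vector (`n_anat` ROI volumes),
and covariates.

- **Connectivity model.** Each group has a target correlation matrix built
  from a shared random base; *planted edges* `(i, j, delta)` raise the
  case-group correlation of edge `(i, j)` by `delta` (validity of the
  resulting matrix is checked; out-of-range deltas raise). Time series are
  drawn from the group's matrix via its Cholesky factor, then perturbed by
  per-site additive offsets (`site_effect_sd`) and subject noise.
- **Anatomy.** Volumes are standard normal per ROI with planted case
  shifts `(roi, delta_sd)` in units of the ROI's standard deviation.
- **Ground truth** (`GroundTruth`) records exactly which edge and
  anatomical features were planted, as feature names, so recovery can be
  scored mechanically.
- **External cohorts** (`CohortShift`) reuse the source disease model but
  change the sample size, sex ratio, per-site offsets, and the random
  stream — modelling a new scanner/site, not a new disease.

Scope: the generator produces *stationary Gaussian* time series; it makes
no attempt at hemodynamics, autocorrelation structure, motion artifacts,
or realistic anatomical covariance. It is a test harness for the analysis
protocol, not a brain simulator.

## 2. Connectome features

- **Covariance shrinkage.** Per-subject covariances use analytic shrinkage
  toward the diagonal (Schäfer–Strimmer style, intensity estimated from
  the data, clipped to [0, 1]). This keeps matrices SPD even when
  `n_timepoints < n_rois`, which the tangent machinery requires.
- **Geometric mean.** The affine-invariant (Karcher) mean of the training
  subjects' covariances, computed by fixed-point iteration
  `G <- G^{1/2} exp(mean_k log(G^{-1/2} C_k G^{-1/2})) G^{1/2}` with
  tolerance 1e-7 on the Frobenius norm of the mean log, max 200
  iterations, and step-halving if the residual increases. Non-convergence
  raises `GeometricMeanError` rather than returning a bad reference.
- **Tangent embedding.** `S = logm(G^{-1/2} C G^{-1/2})`, computed by
  eigendecomposition of the symmetrized whitened matrix. Edge features are
  the strict upper triangle in row-major order, named `edge_i_j`.
- **Leakage control.** `FeaturePipeline.fit(train_idx)` computes the
  reference mean, anatomical scaler, and site category list from training
  subjects only; `transform` applies them frozen. The pipeline carries a
  SHA-256 checksum over its fitted state; external-validation entry points
  compare checksums and raise `LeakageError` on mismatch. Unseen external
  sites produce a warning and an all-zero site encoding.

## 3. Split protocol and model search

- **SplitPlan.** One stratified 80/20 train/test split plus 3 CV folds of
  the training set, stratified jointly on diagnosis x sex (falling back to
  diagnosis-only with a warning when a cell is too small). Integer
  allocation uses largest remainders; leftover subjects are dealt
  cyclically so fold sizes differ by at most 1. The plan serializes to
  JSON and carries a checksum; every `SearchRecord` stores it, making
  "all families saw the same data" auditable.
- **Search.** For each (family, feature set), `n_configs` configurations
  are drawn from the family's declared space (log-uniform for scale
  parameters, uniform/integer otherwise; per-draw seeds < 2^31). Each is
  scored by mean 3-fold CV AUROC; the best (ties broken by draw index) is
  refit on the full training set and scored once on the held-out test set,
  filling one cell of the family x feature-set `ResultMatrix`. A JSONL
  journal makes runs resumable; re-running with the same seed is
  byte-identical. The connectome CNN only accepts square connectivity
  input, so its non-functional cells are recorded as NaN with a reason.
- **Deep training.** Networks train with Adam (lr 1e-3, batch 32, up to
  120 epochs) and early stopping (patience 15, min-delta 1e-5) monitored
  on an internal 10% stratified sliver of the training data, restoring the
  best weights. The autodiff engine is reverse-mode over numpy arrays;
  every operator's gradient is checked against central finite differences
  in the test suite.

## 4. Importance and significance

- **Permutation feature importance (PFI).** For a fitted model and the
  held-out test set, a feature's importance is `AUROC(before) −
  AUROC(after shuffling that column)`, repeated 64 times. Each feature's
  permutation stream is keyed by a CRC of its name, so results are
  invariant to which other features are analyzed. z-scores are computed
  across features within a model.
- **Null distribution.** The model is refit `n_label_perms` times (default
  20) on label-permuted training data, and PFI is recomputed against
  label-permuted evaluation labels; each refit contributes one *mean*
  importance per feature. This is a response-permutation null in the
  spirit of PIMP: it captures both permutation noise and between-refit
  baseline variability.
- **Test statistic.** For each feature, the observed mean importance over
  64 reps is compared to the null refit means with
  `t = (obs − mean_null) / (sd_null · sqrt(1 + 1/n_null))`, one-tailed,
  `df = n_null − 1`, i.e. a predictive t-test of "is the observed mean a
  plausible draw from the null means". An earlier pooled Welch test that
  compared the 64 (correlated) reps against the pooled null values was
  badly anticonservative — on no-signal cohorts it declared ~48% of
  features significant; the calibrated statistic declares 0.25% at BY 1%
  (measured over 10 seeded null cohorts, enforced ≤2% by the test suite).
  Features with numerically degenerate reps or null get p = 1.
- **FDR.** Benjamini–Yekutieli at 1% (statsmodels `fdr_by`), valid under
  the arbitrary dependence that tangent edge features exhibit. BY's
  `log(m)` penalty makes it conservative at desk scale; discovery flows
  mainly through the consensus ranking below, with BY reserved for
  calibrated type-I claims.
- **Consensus.** Each of the top-N models (by CV AUROC) yields a z per
  feature; features are ranked by median z. A *star* marks z ≥ 3 in all
  models, a *diamond* z ≥ 3 in all but one. Direction marks (+/−/o) come
  from a univariate Welch t-test of the feature in cases vs controls on
  the test set at alpha 0.05.

## 5. Hyperparameter landscape

The top quintile of scored configurations (by CV AUROC) is density-
estimated with a Gaussian KDE over the requested dimensions (log-scaled
dimensions are estimated in log10 space); the peak is the argmax over a
64-point grid per dimension. Dimensions that are constant within the top
quintile get their analytic value as the peak (KDE would be singular). A
peak is boundary-flagged if it lies within 5% of the search range's edge
— a sign the space should be widened. Fewer than 10 scored records is an
error; an all-tied top quintile is reported as degenerate rather than
invented.

## 6. External validation

- **Transfer.** Source models score the external features produced by the
  frozen source pipeline; mean and per-model AUROC are reported.
- **Domain adaptation.** 10 folds are drawn stratified on the external
  labels. For each fold, the model is fine-tuned on that fold's 10% tuning
  split (Adam at the base learning rate, early stopping monitored on the
  same split — at 10–40 tuning subjects a further sub-split proved too
  small to monitor anything) and scored on the remaining 90%. Classical
  models have no warm start; they are refit from scratch on the tuning
  split and the result is flagged `refit_from_scratch`. Zero-epoch
  adaptation reproduces plain transfer fold-by-fold exactly, which the
  tests verify; this pins down that any adaptation gain comes from the
  fine-tuning itself.
- **Concordance.** Pre- vs post-adaptation PFI vectors are compared by
  Pearson and Spearman correlation over features selected by a z-threshold
  rule (union by default; the intersection alternative is reported
  alongside). Fewer than 3 shared features yields NaN with a flag.

## 7. Determinism and seeds

A single master seed is fanned out through `numpy.random.SeedSequence`
into named stage seeds (`cohort`, `split`, `search`, `importance`,
`external`), all < 2^31. Every stochastic component takes an explicit
seed; no global RNG state is used. The run manifest records seeds,
configuration, and SHA-256 checksums per artifact.

## 8. Resolved design questions

- *Null evaluated against true or permuted labels?* Permuted (response
  permutation). Evaluating null refits against true labels made the null
  far too wide on signal-bearing cohorts (planted features at z ≈ 9 got
  p ≈ 0.37), destroying power without improving calibration.
- *Fine-tuning learning rate.* Full base rate, with early stopping as the
  regularizer. A reduced rate (lr/5) failed to move weights usefully in
  the few epochs tiny tuning splits allow.
- *Stratification fallback.* Joint diagnosis x sex strata when every cell
  supports at least one subject per fold, otherwise diagnosis-only with a
  logged warning — silent degradation would invalidate fairness claims.

## 9. Limitations

- The generator's Gaussian stationary signal is much easier than real
  fMRI; absolute AUROC values here say nothing about clinical performance.
- BY at 1% on desk-scale cohorts has low power; significant-feature counts
  near zero are expected and honest.
- The LSTM consumes time series in 8 fixed chunks and the CNN assumes a
  square connectivity matrix; neither handles variable-length input.
- Domain adaptation assumes some labelled external data (10% per fold);
  fully unsupervised adaptation is out of scope.
- The in-repo autodiff engine is single-threaded numpy; it is sized for
  hundreds of subjects and tens of ROIs, not biobank scale.
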