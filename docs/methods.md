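# Methods

This note documents the models, conventions and numerical choices behind
`sskeca`, in the spirit of a package's own methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting

Free-viewing eye tracking distinguishes people with schizophrenia (SZ)
from healthy controls (HC): during unconstrained viewing of semantic
images, SZ cohorts show reduced saccade velocity and amplitude, narrower
exploration, and blunted pupil dynamics. The package turns segmented
eye-movement events (fixations, saccades, blinks, gaze samples) from a
protocol of 100 images x 5 s (preceded by a 1.5 s fixation cross, 800x600
display) into a per-trial 24-dimensional feature vector, transforms the
feature matrix with a sparsity-scoring kernel entropy component analysis
(SSKECA), classifies trials, and aggregates each subject's trial
predictions into a diagnosis by majority vote.

The reference cohort (40 SZ / 50 HC) is private; its published group
summaries (per-feature mean +- SD per group, demographics, a gender
contingency table) are shipped in `sskeca.calibration` and serve both as
worked-example inputs for the statistics helpers and as the default
targets of the synthetic generators.

## Event cleaning

Rules, in attribution order: (1) fixations outside the display
(half-open pixel bounds, origin top-left) are removed; (2) saccades with
amplitude < 1 deg are removed as microsaccades; (3) fixations shorter
than 80 ms or longer than 2000 ms are removed. Each removal is charged
to the first matching rule, making `CleaningStats` deterministic. A
per-saccade "1-2 Hz" microsaccade-frequency criterion is not well
defined on segmented events; with `apply_frequency_filter` enabled the
trial-level saccade rate is annotated instead of removing anything.
Saccade events in our dialect carry no coordinates, so the
outside-display rule applies to fixations only.

## Feature conventions

Most of the 24 features are direct sums/means/extrema over cleaned
events. Conventions that required a decision:

- **Saccade amplitude** is the per-trial *sum* of amplitudes. The
  reference HC mean (132.73 deg) is impossible as a per-saccade value
  but matches ~13.8 saccades x ~9.6 deg.
- **Pupil dynamic range** `(max - min)/avg` and **size ratio**
  `max/avg`: both definitions reproduce the reference group means from
  the printed min/avg/max pupil means (0.36 and 1.15 for HC; 0.30 and
  1.13 for SZ), which is the evidence for adopting them.
- **Fixation skewness** is the mean Euclidean distance of cleaned
  fixation centroids from screen centre - a central-bias statistic whose
  scale (~160 px on 800x600) matches the reference values. It is the
  simplest statistic consistent with "central bias of the fixation
  distribution"; it is exposed as its own function so an alternative
  definition can be swapped in.
- **Valid viewing duration** sums all fixations landing inside the
  display *before* duration-based cleaning; **fix duration** sums only
  cleaned fixations. The reference table prints VVD (~4708 ms) > total
  fixation duration (~3789 ms), so the two cannot share one definition;
  this pair makes VVD >= fix duration structural.
- **Outside fixation count** is computed on the pre-cleaning record
  (cleaning removes those fixations; the feature still observes them).
- **Sample count** counts valid gaze samples at one per millisecond of
  binocular-equivalent recording (the reference value ~6804 tracks the
  recording duration in ms, not the 500 Hz mono rate).
- Degenerate trials: zero saccades or blinks give zero-valued features;
  a trial with no cleaned fixations or no valid samples is flagged
  invalid and dropped from the feature table.

Group statistics (Welch t with Satterthwaite df, pooled-SD Cohen's d,
Yates chi-square) are computed from summaries by the textbook formulas
and reported with raw p-values (no multiplicity correction), HC minus SZ
sign convention. Sample-level rows are the default unit of analysis;
`by_subject=True` averages trials per subject first. One printed
demographic statistic (age, t = 2.18) cannot be recovered from its own
summaries under either Welch or pooled t and is excluded from the
worked examples.

## The SSKECA transform

Steps: population-SD z-scoring; adaptive RBF bandwidth
`BW = w * sigma1 / D` (sigma1 = largest singular value of the
standardized matrix; `w` defaults to 1; an explicit override such as the
reference study's fixed BW = 3.948 short-circuits the rule); RBF kernel;
double-centering `Kc = H K H`; symmetrized eigendecomposition with
relative eigenvalue filter `tol = 1e-10` (negatives always dropped);
sparsity scoring; top-`ncomp` selection (ties to the larger eigenvalue);
projection `Xtrans = Kc Asel (Lambda_sel + delta)^{-1/2}` with ridge
offset `delta = 1e-12`.

**The entropy-alignment choice.** The textbook entropy contribution of a
kernel eigenpair is its alignment with the all-ones vector,
`G_i = lambda_i (e_i' 1)`. That quantity is *identically zero* on a
double-centered kernel: `Kc 1 = 0`, so every retained eigenvector is
exactly orthogonal to `1`, and a score `G_i - beta ||alpha_i||_1` built
on it collapses to pure l1 minimization - which empirically selects
spiky, small-eigenvalue noise components and destroys class signal (we
measured chance-level accuracy). SSKECA therefore measures the alignment
against the training mean kernel row `kbar = K 1 / N` of the
*uncentered* kernel: `G_i = lambda_i (e_i' kbar)`, eigenvector signs
fixed so the alignment is non-negative. For an uncentered kernel
`e' K 1 = lambda (e' 1)`, so this reduces to the classical quantity up
to a positive per-component factor, while remaining informative after
centering. `sparsity_scores` keeps the all-ones default so the textbook
form is still available as a standalone operation. The KECA baseline
uses the same alignment, squared (`lambda_i (e_i' kbar)^2`); KPCA ranks
by eigenvalue; PCA is an SVD on the centered matrix. All four share the
fit/transform contract.

Out-of-sample rows are projected Nystrom-style: kernel rows against the
training set, centered with the stored *training* column means and grand
mean, then projected on the selected eigenvectors. This is what makes
cross-validation leak-free; on training rows it reproduces the training
projection to machine precision (tested at 1e-8).

Defaults: `beta = 0.01` (mild l1 penalty; `beta = 0` is entropy-only
ranking), `ncomp = 21` in the shipped pipeline (the dimensionality the
reference study found best for its AdaBoost pairing); `ncomp="grid"`
selects by inner subject-level CV accuracy instead. An optional lasso
post-stage (off by default) zeroes transformed coordinates whose
l1-regularized coefficient against the class label vanishes; it never
affects default behaviour.

## Classification protocol

Subjects are partitioned into k = 5 stratified folds (seeded shuffle
within class, round-robin deal), so 40 SZ + 50 HC gives exactly 8 SZ +
10 HC per test fold. Per fold, the transform is fitted on training rows
only and applied to test rows; the classifier (AdaBoost by default; RF,
KNN, SVM, MLP, XGBoost, LightGBM available with library-default
hyperparameters and derived seeds) is fitted on the transformed training
rows. A CNN variant is not provided - no deep-learning framework is a
dependency of this package, and no architecture is specified for
24-dimensional tabular input.

A subject is voted SZ iff the fraction of SZ-labelled samples strictly
exceeds the 50% threshold (an exact tie is HC, because "exceeds" is
strict). Metrics (accuracy, precision, recall, F1 with SZ positive, and
AUC scored by the subject's vote fraction) are reported as mean +- SD
across folds with 95% BCa bootstrap intervals (B = 1000, jackknife
acceleration, deterministic seeds) over pooled subject-level outcomes.
A zero-variance jackknife falls back to the percentile interval with a
warning; degenerate resamples where a metric is undefined (one-class
AUC) are dropped from the bootstrap distribution. AUC uses the
Mann-Whitney rank form (verified against `sklearn.metrics.roc_auc_score`
in tests); the hand-rolled BCa is verified against
`scipy.stats.bootstrap(method="BCa")` and by a coverage simulation
(~95% on a normal mean, n = 100).

## Ablation importance

Feature importance is delta-ACC: baseline accuracy minus the accuracy of
the identical pipeline (same fold plan, same seeds) re-run with one
feature removed, measured at sample level and at voted subject level.
Total importance is the sum; a feature is "retained" iff the total is
strictly positive (zero excluded). The default masks a feature by global
column removal; an `impute` mode replaces it with the column mean
instead, simulating per-subject missing data. Sharing the fold plan
between baseline and every ablation run is essential - otherwise
delta-ACC confounds fold noise with feature contribution.

## Semantic stimulus analysis

Per-image and per-category accuracy are computed from the pooled
out-of-fold sample predictions of the baseline run (no per-image
retraining). Images with accuracy >= 0.85 (inclusive threshold) form the
reduced stimulus set; selection is per image, with categories as a
reporting grouping, because category-level maxima need not clear an
image-level threshold. The reduced set is re-evaluated with the same
fold plan, so the comparison isolates the stimulus reduction; a subject
left without samples aborts with an error naming the subject.

## Synthetic cohorts

`generate_feature_table` draws each feature from a Gaussian two-level
model: subject effect (SD tau) plus trial noise (SD sigma_w). The split
is calibrated so that **the SD of per-subject trial means equals the
reference group SD** (`tau^2 + sigma_w^2/m = SD^2`, m = trials/subject)
and the intraclass correlation `tau^2/(tau^2 + sigma_w^2)` equals `icc`
(default 0.5). The reference summaries behave as subject-level
statistics - recomputing Welch t from per-subject means at n = 50/40
reproduces the reference t-values (tested within +-0.5 averaged over
replicates) - which is why the calibration anchors the subject-mean
variance rather than the per-trial variance. Consequences worth noting:
per-trial SD is `sqrt(tau^2 + sigma_w^2)` (about 1.4x the group SD at
icc = 0.5, m >= 10), and at icc = 0 subject means still have the target
SD while trial draws are sqrt(m) times noisier.

Structural couplings: min/avg/max triples (fixation duration, pupil
size) share a latent factor (loading 0.95) and are order-enforced per
row; pupil DR and SR are recomputed from the generated min/avg/max; VVD
is floored at the total fixation duration; counts are rounded to
non-negative integers (upward-biased for near-zero means such as the
outside-fixation count, ~0.5); fixation count is floored at 1. Features
are otherwise independent (the reference publishes no between-feature
correlations); a heavy-tailed option (scaled t5) sits behind a flag.

`generate_trials` synthesizes full event streams per trial from a latent
feature row: fixation durations summing exactly to the total (each in
[86, 1990] ms, surviving cleaning by construction), centroids at the
exact target mean distance from centre, exact-mean tracker resolutions,
saccades with unit-floor amplitudes summing to the target and exact mean
velocity/duration, a 1 ms pupil trace with exact min/mean/max and a
unique maximum at the target gaze position, plus deliberately cleanable
events: outside-display fixations realizing the outside-fixation count
and sub-80 ms filler fixations realizing VVD minus fix duration. The
reference summaries are *not jointly realizable* by any single event
stream (the printed average fixation duration, 375 ms, contradicts
total/count = 283 ms), so the order-statistic fixation-duration features
are emergent rather than targeted; everything else round-trips through
`extract_features` to the latent targets (tested per trial at 2-5%).
Infeasible draws (e.g. total duration below the per-fixation floor) are
clipped rather than resampled, which slightly biases the affected rare
trials.

What the generator does **not** emulate: scanpath dynamics, image-content
dependence of gaze, between-feature correlation beyond the enforced
couplings, non-Gaussian marginals (by default), and any medication or
symptom structure. Passing pipeline tests on this cohort shows the
machinery recovers planted group structure under the published effect
sizes; it does not validate the clinical claim on real recordings.

## Problem sizes and determinism

End-to-end stochastic checks (test suite and acceptance script) run the
full 90-subject cohort geometry at 20 trials per subject - the kernel
eigendecomposition is O(N^3) in the number of training samples, and 20
trials already gives each subject a meaningful vote while keeping a
20-seed sweep tractable on one CPU; worked-example and fold-geometry
checks use the exact published n. A single run seed fans out to
per-stage child seeds via `SeedSequence` over a CRC of the stage label,
so toggling one optional stage never shifts another stage's randomness;
every artifact (tables, event CSVs, reports) is byte-reproducible from
(config, seed).

## Known limitations

- The entropy-alignment repair above is this package's design choice;
  an implementation that scores uncentered-kernel eigenpairs instead
  would be a different (also defensible) reading of the method.
- BCa intervals at 90 subjects with strongly discrete metrics
  (accuracy steps of 1/90) inherit the usual bootstrap discreteness.
- The CSV event dialect has no per-sample validity column; invalid
  samples are encoded as an empty pupil cell.
- `ncomp="grid"` re-runs the inner CV per candidate dimensionality and
  is expensive; the shipped default is the fixed value 21.
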