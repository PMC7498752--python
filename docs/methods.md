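# Methods

This note documents the statistical procedures implemented in `eegmvpa`,
the conventions chosen where several were defensible, and what the
synthetic-data generator does and does not emulate.

## Synthetic epoched EEG

The generator (`eegmvpa.simulate`) emulates a passive-viewing visual
paradigm: `n_conditions` stimuli (default 8) split into categorical
domains (default 2 × 4, e.g. animals vs body parts), epochs of
−50..500 ms around stimulus onset.

**Signal.** Each condition elicits a spatial pattern over channels.
Base patterns are drawn once per configuration with a prescribed
correlation structure — `within_domain_similarity` (default 0.5) between
same-domain conditions, `across_domain_similarity` (default 0.2)
otherwise — by factorizing the target correlation matrix (an error is
raised if it is not positive semidefinite). Each simulated subject
receives the base patterns rotated by a Haar-random orthogonal map:
rotations preserve all pairwise pattern geometry, so every subject
expresses the *same* representational structure through an
*idiosyncratic* channel topography. This is exactly the regime that
motivates within-subject rather than cross-subject classification.
Patterns are unit-norm and scaled by `snr × 10 μV`; the temporal profile
is a raised cosine over `signal_window` (default 80..400 ms), chosen as
the simplest smooth evoked-response-like envelope.

**Noise.** Stationary AR(1) in time (coefficient default 0.9) with
spatially correlated Gaussian innovations (uniform channel correlation,
default 0.3), scaled to sd 10 μV — a typical amplitude scale for
average-referenced scalp EEG. `snr` is therefore the ratio of pattern
norm to noise sd; `snr=0` yields label-free null data. AR(1) with
correlated innovations is the simplest model with EEG-like temporal and
spatial autocorrelation; it does **not** reproduce 1/f spectra,
oscillations, non-stationarity, volume-conduction topographies or
age-specific skull/cortex differences. Passing tests on these data
demonstrate the statistical correctness of the pipeline, not performance
on real recordings.

**Artifacts.** Each trial independently becomes an artifact trial with
probability `artifact_probability`; one random channel receives a 20-ms
pulse of magnitude 1.2–1.5 × `artifact_amplitude` (default 200 μV), so
artifact trials reliably exceed the rejection thresholds while clean
trials essentially never do.

**Determinism.** All outputs are bit-reproducible given
`(seed, subject_index)`; subject streams are independent.

## Preprocessing conventions

Stage order is fixed: smooth → baseline-correct → reject → select
channels → z-score.

- *Smoothing*: centered running average (default 20 ms); the window
  shrinks at epoch edges rather than padding, so no data outside the
  epoch are fabricated.
- *Windows*: all ms intervals are half-open `[lo, hi)`; the baseline is
  `[-50, 0)` so the sample at onset is excluded.
- *Rejection*: "exceeded ±X μV" is read strictly — a sample exactly at
  the threshold is kept. Per-channel thresholds (e.g. frontopolar ±60 μV,
  horizontal EOG ±40 μV) are applied before those channels are dropped
  from the feature set, so EOG channels can veto trials and then be
  removed.
- *Z-scoring*: per trial and channel against the trial's own baseline,
  sample (ddof = 1) standard deviation. A flat baseline (sd below
  1e-10 relative tolerance — a railed channel yields sd ≈ 1e-15·mean in
  floating point, never exactly 0) invalidates the trial rather than
  producing non-finite features.
- *Inclusion*: a participant is retained when valid trials ≥ 50 % of the
  maximum possible. `subsample_trials` yokes trial counts across groups
  by uniform subsampling without replacement.

## Decoding

Features are the channel z-scores at a single timepoint. For a condition
pair, each repeat randomly permutes each condition's trials, partitions
them into `n_folds` (default 4) near-equal folds (sizes differ by ≤ 1;
the two conditions are partitioned independently, so pseudo-trials may
average unequal trial counts), and averages each fold into one
pseudo-trial. The classifier is a soft-margin linear SVM with hinge loss
and fixed C = 1.

`fold_rotation=True` (default) tests each fold in turn within a repeat
and averages; `False` holds out only the last fold, the literal
single-test-fold scheme. Both are unbiased because fold membership is
re-randomized every repeat; rotation has lower variance. Random streams
derive from `(seed, cond_a, cond_b, repeat)`, so pairs are independent
and each subject receives its own seed (`pipeline.subject_seed`).

**Batched solver.** A full analysis trains on the order of 10⁶ SVMs, each
on ~6 pseudo-trials; per-call overhead of generic SVM interfaces
dominates at that size. `eegmvpa.svm` therefore solves the standard
C-SVM dual with a vectorized SMO sweep for an entire batch of problems
(all timepoints and folds of a repeat) at once. The solver targets the
same optimum as libsvm; the test suite asserts agreement of weights,
bias and predictions with `sklearn.svm.SVC(kernel="linear", C=1)` on
random problems. Ties at a decision value of exactly 0 predict the
positive class.

Multiclass decoding is one-vs-one voting over all pairs of conditions
(ties go to the lowest condition id); chance is 100/k %. Temporal
generalization reuses the same pseudo-trial partition across all train
and test times within a repeat, so its diagonal reproduces the
timecourse procedure exactly at matched seeds. The Haufe transform
a = Σ·w uses the covariance of the training pseudo-trials of the same
repeat and timepoint; patterns are averaged over repeats and folds.

## Cluster-corrected sign-permutation inference

The point statistic is the across-subject mean of (value − null_value)
— 50 for accuracies, 0 for paired differences. The permutation scheme
flips the sign of each subject's entire series; all 2ⁿ assignments are
enumerated when 2ⁿ ≤ `n_permutations` (true for typical group sizes of
8–10), otherwise a seeded random subset is drawn.

- Pointwise p-values use the add-one rule (1 + #{perm ≥ obs})/(1 + N);
  comparisons carry a 1e-9 relative tolerance so the identity
  assignment, whose statistic equals the observed one up to
  summation-order rounding, always counts. With exhaustive enumeration
  this makes p-values slightly conservative (the identity is counted in
  the null *and* by the add-one), and the smallest attainable cluster
  p is 2/(N+1).
- Clusters are maximal runs (1D) or 4-connected components (2D) of
  positions whose pointwise p ≤ `cluster_alpha` (default 0.05). The
  cluster statistic is the mass — the sum of point statistics in the
  cluster (|statistic| for two-sided tests, preserving sign symmetry);
  extent is available as an option. Mass was chosen as the more
  sensitive, most commonly used variant.
- The null distribution is the maximum cluster statistic per
  permutation, thresholded identically to the observed map; cluster
  p-values are add-one proportions. Clusters with p ≤ 0.05 are flagged
  significant; 0.05 < p ≤ 0.10 marginal.

Negating *one* subject's series leaves the permutation null unchanged
(the sign-flip group is closed under negation) but moves the observed
statistic to a different member of the orbit, so observed p-values are
not invariant to it; negating *all* subjects leaves two-sided p-values
identical. FDR correction is Benjamini–Hochberg step-up (via
statsmodels); empirical p-values against sampled nulls use the add-one
rule and are never 0.

## RSA

Decoding RDMs hold window-averaged pairwise accuracy (diagonal NaN);
model RDMs are 1 − Pearson r of activation vectors or 1 − SSIM of
stimulus images (diagonal 0). All RDM comparisons use strictly-upper
triangles (28 values for 8 conditions).

**Noise ceiling.** For each of `n_splits` (default 100) random
half-splits of the subjects (⌊n/2⌋ vs the rest), the two half-group mean
RDMs are Pearson-correlated and corrected with √(2r/(1+r)) — the square
root of the Spearman-Brown formula, mapping full-group reliability back
to the single-half correlation scale. Negative split correlations are
floored to 0 *per split* before averaging; the flooring locus is
ambiguous in principle, and the per-split choice keeps the null
procedure well defined. The empirical null repeats the entire procedure
`n_null` (default 10,000) times with one half's group RDM scrambled in
every split — scrambling permutes the upper-triangle dissimilarities and
mirrors them, which destroys structure while preserving the value
distribution (permuting condition rows/columns jointly is the main
alternative; entry permutation is the stronger scramble).

Group-RDM similarity uses Pearson correlations with two-sided parametric
p-values; the FDR family is all between-RDM correlations plus all noise
ceilings (15 + 6 = 21 for 2 groups × 3 windows). Model comparison uses
Spearman rank correlations (no linear relation between neural and model
dissimilarities can be assumed) with FDR over the full
groups × models family (18 for 6 × 3). Domain contrasts compare each
subject's mean across-domain vs within-domain dissimilarity with a
two-sided paired t-test per window, FDR over windows. Default analysis
windows: 100−190/200−300/300−500 ms (infants) and
80−120/150−190/250−400 ms (adults).

**SSIM.** `skimage.metrics.structural_similarity` with the canonical
published parameterization: 11×11 Gaussian window (σ = 1.5), K1 = 0.01,
K2 = 0.03, population covariance; color images are converted to
luminance first. ssim(A, A) = 1 identically.

## ERP analysis

ERP statistics consume baseline-corrected, artifact-rejected, *non*
z-scored epochs in μV. ROI averaging and component-window amplitudes are
plain means. The domain effect on a component amplitude is a paired
comparison of per-subject domain means reported as F = t² with
df (1, n−1); for two domain levels a mixed-effects ANOVA of the domain
fixed effect reduces to this paired test. (Published analyses of
comparable designs sometimes report denominator df suggesting a
different random-effects coding; with two levels the paired test is the
canonical choice and the one implemented.) Waveform comparisons delegate
to the two-sided 1D cluster test with null value 0.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at
reduced sizes chosen to exercise every code path with stable statistics:
chance calibration uses 8 subjects × 8 conditions × 12 trials ×
50 timepoints (100 Hz) × 20 repeats; family-wise error uses 200 null
replicates of 10 subjects × 100 timepoints with exhaustive 2¹⁰
permutations; parameter-recovery checks (accuracy > 90 %, geometry
Spearman > 0.5) use the high-SNR regime snr = 5 with 40 trials per
condition. Production analyses would use the full 200 repeats and
10,000-null ceilings; all of these are plain parameters.

## Known limitations

- The generator's noise is Gaussian AR(1); real EEG artifacts
  (blinks, saccades, movement) have structured topographies and
  non-Gaussian amplitude distributions.
- Only linear classifiers and time-locked voltage features are
  implemented; induced oscillatory features and nonlinear kernels are
  out of scope.
- Cross-subject decoding is deliberately unsupported; the design is
  within-subject throughout.
- Cluster inference assumes per-subject effect symmetry around the null
  value under H0; heavily skewed subject effects would violate the
  sign-flip exchangeability.
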