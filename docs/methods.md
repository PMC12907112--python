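# Methods

`tgdecode` implements a cross-task temporal-generalization MVPA pipeline for
epoched EEG: does the multivariate pattern that separates rare targets from
frequent standards in an oddball task transfer to the target/load contrasts
of an n-back working-memory task, and does that transfer concentrate in the
P300 window over parietal/occipital sensors?  Because the original
recordings are an external download, the package ships a synthetic study
generator that reproduces the design's structure, so every stage is testable
end to end.  This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic results do and do not show.

## Decoding model

For one subject and one condition pair, trials are epochs
`X ∈ R^{trials × channels × time}` (µV).  Each of `n_reps` (default 100)
repetitions proceeds as:

1. **Under-sampling.** The majority condition is subsampled without
   replacement to the minority count, removing class-imbalance bias.
2. **Pseudo-trials.** Each condition's trials are shuffled and averaged in
   groups of `k` (default 4; 2 and 6 exposed as robustness variants),
   raising SNR by √k at the cost of sample count; the `⌊n/k⌋` remainder is
   dropped.
3. **Stratified k-fold CV.** Pseudo-trials of each condition are split into
   `n_folds` (default 4) folds; each fold serves once as the test set.
4. **Per-time-point classification.** At each time point the feature vector
   is the channel pattern.  Features are z-scored per channel with
   training-fold statistics only.  The classifier is a linear SVM with
   C = 1 (`sklearn.svm.LinearSVC`, liblinear; chosen over the libsvm
   backend for a ~4x faster fit at indistinguishable accuracy on these
   standardized, low-dimensional problems; `random_state` pinned because
   liblinear's dual solver is stochastic).  Held-out accuracy is averaged
   over folds, then repetitions.  Chance is 0.5.

**Temporal generalization (TGA)** tests each per-time-point classifier at
every other time point, yielding a train × test accuracy matrix whose
diagonal is the time-course result.  Both operations consume one seeded
resampling stream in the same order, so with a shared seed the diagonal
identity holds exactly (bit-for-bit), which the tests assert.

**Cross-task transfer** trains at each time point of task 1 on *all* of its
pseudo-trials and tests on all pseudo-trials of task 2 at every time point
(matrix A), then reverses the roles (matrix B); the shared-representation
matrix is `(A + Bᵀ)/2`.  No CV is used by default — train and test sets are
disjoint by construction; a `cross_task_cv` flag adds k-fold CV on the
training task for users who want it.  Class correspondence across tasks is
positional (the target-like condition first in both pairs).  Two
standardization details matter here:

- each task is z-scored with its *own* class-pooled per-channel statistics
  (training task at the training time point, test task per test time
  point).  Pooling over conditions leaks no label information, and
  task-specific centering removes the between-task offset of the common
  ERP mode — without it, a classifier calibrated on one task's feature
  distribution systematically mislabels the other task's samples even when
  the discriminative direction transfers perfectly;
- per repetition the two tasks draw from identically-seeded streams, so
  the degenerate case "task 2 = task 1" yields A = B and an exactly
  symmetric shared matrix (a structural test).

**Peak extraction** restricts a result to its largest significant cluster
(largest |mass| when a cluster result is supplied, largest extent for a
plain mask), intersects it with the P300 window (closed interval, both axes
for matrices), and reports the maximum accuracy with its latency (train and
test latencies for matrices).  An empty intersection is an explicit
"not found" result, never an exception.

## Cluster-based permutation tests

Significance of decoding scores against chance uses the max-statistic
cluster permutation test: per-point one-sample t (one-sided for decoding),
cluster-forming threshold at α = 0.05, cluster mass = sum of t values,
adjacency = temporal neighbours (1-D) or orthogonal 4-connectivity (2-D
generalization grids).  The null flips the sign of each subject's
(score − chance) profile; each permutation contributes its *maximum*
cluster mass, which controls family-wise error.  The sensor-space variant
uses paired t values over electrodes, two-sided with sign-consistent
clustering, a ≥2-electrode minimum extent, and electrode adjacency from
Delaunay triangulation of the azimuthal-equidistant-projected montage.

Numerical choices:

- `p = (1 + #{null ≥ observed}) / (1 + n_perm)` for random permutations
  (valid, never zero); when `2^n_subjects ≤ n_perm` the sign assignments
  are enumerated exhaustively and `p = count / 2^n` with the identity
  included — the tests exploit this to check Monte-Carlo p against a
  brute-force oracle exactly.
- Zero-variance points get t = 0 and can never join a cluster.
- Sign flips leave per-point sums of squares invariant, so the permutation
  t-maps are computed with a single matrix product per block
  (`t = mean / sqrt((ssq − n·mean²)/(n−1)/n)`).
- Delaunay degeneracies: exactly co-circular quads (where both diagonals
  are valid) are resolved toward the lexicographically smallest diagonal
  by electrode name, making the adjacency reproducible across qhull
  versions.
- Network-level tests Bonferroni-adjust the cluster-level alpha
  (0.05/6 = 0.0083); the cluster-forming threshold stays at 0.05.

## Univariate ERP layer

P300 amplitudes are window means (closed interval; oddball 250–650 ms,
n-back 300–750 ms) of the trial-averaged signal at an electrode (Pz by
default).  Paired comparisons report t, df = n−1, two-sided p, Cohen's
d = t/√n (the paired-differences convention), and a 95% CI for d of
d ± t_{0.975,n−1}/√n.  A pooled-SD d is also computed because
repeated-measures post hoc conventions vary; only the paired convention is
asserted against known values.  The one-way repeated-measures ANOVA is
delegated to `pingouin.rm_anova` (F, Greenhouse–Geisser ε from the level
covariance, GG-corrected p, partial η²); reported dfs are ε(k−1) and
ε(k−1)(n−1), and the package's tests cross-check F, ε and η²_p against an
independent matrix-algebra implementation to 1e−8.  Post hocs are the
package's paired t with Bonferroni-adjusted p = min(1, m·p).

## Synthetic study generator

The generator emulates the two-task design: 26 subjects by default, the 28
scalp channels of the 10-5 montage (positions from mne's standard
template), epochs −200..1000 ms at 200 Hz, and per-condition retained
trial counts fixed at the study's printed means (oddball 107/249; n-back
175 / 47 / 99 / 39 / 86).  `emulate_design` reproduces the trial roster:
3 sessions × 3 series × 20 trials with exact-count 30% target allocation
per series (6 of 20, then shuffled); n-back digit sequences place target
positions first and fill the remaining digits uniformly from 0–9 while
rejecting accidental n-back matches, so the realized target fraction is
exact.

Each trial is a sum of components plus noise.  A component has a spatial
weight map (Gaussian in 3-D electrode distance, max weight 1), a
half-cosine (Hann) temporal bump, a per-task latency, a per-condition
amplitude, and a per-subject multiplicative log-normal gain (σ = 0.2).
The defaults plant:

- an early occipital response (100 ms, width 100 ms, 2 µV in every
  condition — no class information);
- a P300-like parietal component centred on Pz (width 300 ms) at 400 ms in
  the oddball task and 550 ms in the n-back task, so the cross-task
  overlap appears where the n-back (test) time exceeds the oddball
  (train) time — the lower-right triangle of the plotted matrix.

Noise is Gaussian with AR(1) temporal autocorrelation (ρ = 0.9) and
exponential spatial covariance over 3-D electrode distance.  The noise
scale and correlation length (sd 2.0 µV, 45 mm) were calibrated once so
that single-subject oddball peak decoding lands in the 0.7–0.9 range the
pipeline is designed to operate in; with substantially larger noise the
achievable accuracy is capped not by the true SNR but by covariance
estimation error at ~50 pseudo-trials, and the whole downstream chain
degenerates to near-chance.

Amplitudes: the oddball pair uses the study's printed Pz window means
(3.536 vs 1.250 µV).  The n-back amplitudes are calibrated to the study's
*reported decoding peaks* (with-load pairs ~0.67–0.72) rather than its
printed Pz means, because a single-topography linear generator cannot
satisfy both: real recordings decode far better than their Pz mean gap
implies (the multivariate pattern carries information the single-electrode
mean does not).  Consequently the synthetic n-back Pz means exceed the
printed ones; the qualitative ordering (with-load > load-free contrasts,
targets > nontargets) is preserved.  This is the main sense in which the
generator is *not* a surrogate for the real data: passing tests show the
pipeline recovers what was planted, not that the original recordings would
yield the printed numbers.

The null mode draws every condition of a task from one identical
generative distribution (each component gets its across-condition mean
amplitude) and assigns labels only afterwards, making condition labels
exchangeable by construction — the basis of the chance-calibration and
family-wise-error tests.

Other known idealizations: no eye-blink/muscle artifacts (the ±100 µV
rejection operator is exercised with constructed outliers), no 1/f
spectral shape beyond AR(1), no trial-to-trial latency jitter, no
behavioral errors (trial counts already reflect retained trials), and
stationarity across sessions.

## Determinism and seeding

Every stochastic stage takes an integer seed and derives named substreams
via `numpy.random.SeedSequence(seed, spawn_key=...)` (stage × subject ×
repetition), so re-running any stage or the whole pipeline with the same
configuration is bit-identical; result HDF5 files are written without
timestamps so manifest content hashes are reproducible.  The liblinear
solver seed is pinned.

## Problem sizes used in the shipped checks

The package's own calibration checks run at desk scale, chosen for a
single CPU: chance calibration uses 10 null subjects on a 50 Hz decode
grid with 20 repetitions (the script variant runs the full 100 Hz grid);
the family-wise-error check runs 100 null studies of 8 subjects on a
25 Hz decode grid with 24/24 trials and 1000 permutations (the error rate
of the max-statistic test does not depend on grid size or trial counts);
planted-effect recovery runs 20 studies of 10 subjects at a 50 Hz decode
grid with 20 repetitions, testing the oddball→2-back-nontarget transfer
plus the frontal vs parietal/occipital network contrast on a 25 Hz grid
with 10 repetitions.  Study-scale defaults (26 subjects, 100
repetitions, 5000 permutations, full roster × 7 electrode sets) remain
the configuration defaults.

## Limitations

- The generator's amplitude calibration targets decoding operating points,
  not ERP means, for the n-back task (see above).
- Only one-way repeated-measures ANOVA is provided (the design needs no
  more); no mixed models.
- Linear SVM only, per the method being implemented; no nonlinear
  classifiers.
- Sensor-space analyses only; no source localization.
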