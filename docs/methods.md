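# Methods notes

This note documents the models, estimators and numerical choices behind
`actionrsa`, what the synthetic-data generator does and does not emulate,
and the places where the design was genuinely open.

## RDMs and Kendall τA

All dissimilarity structure is stored condensed (upper triangle, row-major)
with a per-pair *evidence* vector. Evidence is the weight carried into every
average: in partial designs (participants arranging 30 of 152 items) a pair's
group value is the evidence-weighted mean over the subjects who measured it;
in full designs all weights are one and the evidence machinery reduces to a
plain mean.

τA uses the full pair count in the denominator, so ties lower the
correlation rather than being renormalized away (τB exists behind a flag but
is never a default). Implementation: the exact integer concordant-minus-
discordant count S is recovered from scipy's τB by multiplying back the
tie-corrected denominator and rounding to the nearest integer — S is
integral and the float error is orders of magnitude below 0.5, so the result
is exact; the test suite checks it against an independent O(m²) count.
Constant vectors get τA = 0 (S = 0 by definition).

## Multiple arrangement

**Arranger model.** A simulated participant embeds the subset's true
sub-RDM by classical (Torgerson) MDS into 2-D, rescales isotropically to the
unit disk, and jitters every coordinate with Gaussian noise σ (default
0.05, about 2.5% of the arena diameter). This models a participant with
perfect knowledge and imperfect motor placement; it does not model
criterion shifts between trials or attention lapses.

**Evidence.** The platform's evidence formula is unpublished; the package
uses a distance-squared utility w = (d/diameter)² per trial (far pairs are
informative relative to placement noise, near pairs are the ones worth
re-sampling) with multiplicative accumulation 1 − Π(1 − w). Two trials at
w = 0.3 reach 1 − 0.7² = 0.51, i.e. just past the 0.5 criterion. Sessions
also carry a trial budget (default 500 for 65 items) mirroring experiment
time-outs; a session ends at the criterion or the budget, whichever first.

**Lift-the-weakest.** The next subset seeds with a minimum-evidence pair
(ties broken toward under-sampled items, then randomly) and grows with the
items whose pairs against the current subset carry the least evidence. With
a fresh session this makes the first subsets cover the whole item set before
any item repeats.

**Inverse MDS.** Reconstruction alternates between (a) one positive
least-squares scale per trial aligning its on-screen distances to the
current global estimate and (b) evidence-weighted re-averaging of the scaled
distances, to a relative tolerance of 1e-6 or 100 passes, then normalizes
the condensed vector to unit RMS (there is no standard definition of
"normalized" arrangement distances; unit RMS makes sessions comparable
across participants). Pairs placed coincident in every trial
(zero weight) fall back to the unweighted mean of their distances. The
estimate is invariant to global rotation/reflection and to rescaling of any
trial's coordinates.

A known ceiling: trials show at most 7–8 items, and 2-D embeddings of
subsets of a higher-dimensional truth distort distances systematically.
With a noiseless arranger on the default (~6-dimensional) ground truth the
reconstruction plateaus near τA ≈ 0.89; τA = 1 is reached exactly when the
truth is 2-D-embeddable. Averaging subjects removes jitter noise but not
all of this projection bias.

## Time-resolved decoding

Pairwise split-half classification per time bin with pseudotrial averaging:
each half's trials per condition are partitioned into ⌈n/5⌉ groups and
averaged (10 presentations → one pseudotrial of 5 per half). Whitening uses
Σ^(−1/2) of a Ledoit–Wolf shrinkage covariance estimated from the *training
half's* raw trials pooled over time bins (a per-bin covariance is available
behind a flag; pooling stabilizes the estimate at these sample sizes). Both
fold directions are scored and everything is averaged over 10 repeats by
default; accuracies stay on the 0–100 scale.

With one training pseudotrial per class the maximum-margin linear classifier
is exactly the perpendicular bisector of the two whitened points; the
package uses that closed form (vectorized over bins) and sklearn's
`SVC(kernel="linear", C=1)` whenever a class has more than one training
pseudotrial. A test verifies the two agree on separable two-point problems.
The SVM cost parameter is fixed at C = 1; with whitened, averaged inputs
the margin is effectively hard and the choice is not sensitive.

## Inference

The group statistic is the mean subject-level τA (or τA² component). Sign
permutation builds the null by flipping each subject's whole series; the
identity pattern is always included, so p = #{null ≥ obs}/P is an exact
randomization p-value and never zero. When 2^n ≤ n_perm all patterns are
enumerated. Corrections: omnibus max-statistic across models, or
max-cluster-sum across time (cluster-forming threshold: per-window
permutation p ≤ 0.05; thresholding the statistic against the per-window
null quantile is equivalent, and the familywise error of the implemented
variant is verified by simulation). Bootstrap onsets resample
subjects with replacement (1000 replicates, 90% central CI); replicates
without a significant cluster are excluded from the CI and counted, and the
result is flagged unreliable past 50% missing.

**Onsets across split iterations.** For the time-resolved variance
partition the "subjects" of the permutation test are split-half iterations,
which share data; the test is therefore descriptive rather than exact. Per-iteration onsets are defined against the
group-level significant clusters: the first window inside the earliest
significant cluster where that iteration's value is positive. Windows
before stimulus onset are never eligible — no effect can causally precede
the stimulus, and the shared-data anticonservativeness would otherwise
admit baseline clusters.

## Variance partitioning

Predictor condensed vectors are z-scored before the OLS fits (predictions
are invariant up to the intercept; verified by test). Regressions include
an intercept since dissimilarities are non-centered. τA² of an
anti-predictive model (τ < 0) still enters as a positive square; such
evaluations are counted (`n_negative_tau_`) and an option zeroes them.
Cross-validation schemes: per-pair estimate splitting (partial designs),
subject splitting, and subject splitting per time window for neural data
(100 iterations by default). Pairs missing from a train half are masked for
that iteration and logged.

## The synthetic study

The generator emulates the study conditions: 18 activity categories × 8
videos + 8 agent-free controls (152 items) or the 65-item replication set
(3–4 per category); five rating dimensions rated 1–5 by 18 raters per
dimension with latent-Gaussian discretization (plantable bad raters:
two-unique-value responders and catch failers); annotations (category,
indoors/outdoors, watermark, 5-effector binary vector, 0–3 agents);
Gaussian embedding features standing in for scene/network descriptors.
Features within a group share a common factor (correlation 0.3 by default).

The behavioral ground truth is Σ_g ρ_g·z(composite_g) + residual, where the
targets (0.02, 0.02, 0.06) are intended unique variances on the τ² scale
and are mapped to weights by Greiner's relation ρ = sin(π·τ/2). The mapping
is exact only for bivariate Gaussians, so planted values steer ordering and
rough magnitude, not exact components (measured noiseless uniques come out
near 0.03/0.03/0.07). The residual is a z-scored distance structure from a
5-dimensional latent — shared, unmodelled behavioral structure; it keeps
the truth approximately embeddable, which pair-level white noise would not.

Epoched recordings map each feature's (z-scored) item values through a
random per-subject channel basis — idiosyncratic topographies — with a
raised-cosine envelope over the feature group's latency window (defaults:
visual 70–270 ms, action 250–500 ms, social-affective 420–720 ms) on top of
spatially correlated Gaussian noise (inter-channel correlation 0.3, white
in time). Ten trials per condition per subject mirror the 10-block design.
The generator does not attempt realistic EEG spectra, eye artifacts, or
video pixel content; recovery results validate the analysis machinery, not
claims about real recordings. Simulated arrangers are also far more
consistent than human participants (leave-one-out τA ≈ 0.9 vs ≈ 0.2 in
human data), because their only noise source is placement jitter.

## Problem sizes used in the packaged checks

The acceptance checks run the behavioral recovery at 65 items with 50
simulated arrangers over 20 study seeds, the temporal recovery at 12
conditions, 32 channels, 50 Hz bins and 10 subjects over 10 seeds, the
calibration suite at 500 null datasets of 20 × 100, and the decoding chance
check over ~10,000 pair-bins; `scripts/acceptance.py` uses the same designs
with fewer replicate seeds. These sizes were chosen to make the qualitative
recoveries stable while keeping a full run on the order of minutes.

## Known limitations

- The evidence formula and subset scheduler are documented interpretations
  of an unpublished adaptive procedure, validated by recovery behavior only.
- The Horn–Schunck defaults (α = 1, 100 iterations) oversmooth small moving
  regions; recovering metric displacement magnitudes needs smaller α and
  more iterations, as the tests demonstrate.
- The rating-reliability estimator (random split-half over raters, Spearman,
  100 splits) is one reasonable choice among several; alternatives such as
  intraclass correlation would rank features similarly but not identically.
- Hue is averaged circularly (saturation-weighted within frames); fully
  desaturated frames report hue 0 by convention.
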