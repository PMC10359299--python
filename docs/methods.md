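# Methods

This note documents the models, the defaults, the numerical choices
and the limits of what the synthetic validation can show.

## Task and design model

The why/how paradigm crosses an inference level (social: *why*;
factual: *how*) with a target stimulus category (*faces*, *hands*,
optionally *nonsocial*), presented in blocks of rapid yes/no trials
(default 8 stimuli per block at a 2 s SOA, 1.75 s response window).
`make_block_design` lays blocks on a fixed timing grid (4 s initial
fixation, 16 s blocks, 4 s inter-block gaps, 8 s final rest; TR 1 s)
with targets interleaved round-robin.  The default 4-blocks-per-
condition, two-target layout mirrors a short single-run localizer;
the 6-block, three-target variant mirrors the longer replication
versions.

**Block order.**  Within each target, why and how blocks are equal in
number and their order is drawn *uniformly at random* from the
balanced arrangements (seeded).  This choice is load-bearing: block
beta estimates from a single GLM share temporal estimation noise
(covariance `(X'X)^-1` restricted to the task columns), and with many
voxels a leave-two-blocks-out SVM can turn any fixed label arrangement
into a large, essentially deterministic accuracy bias of either sign
(we measure a per-arrangement spread of ~19 accuracy points on
1000-voxel null data — the same geometry that makes empirical
permutation null bands on real data span roughly 30–70%).  Averaged
over the uniform ensemble of balanced arrangements the bias is zero to
within 0.1 points, whereas structured ensembles (e.g. strict
alternating pairs) are biased by tens of points.  For the same reason
`simulate_study` gives every simulated participant an independent
balanced order on the common block timing: group-level statistics then
see independent, exchangeable arrangement noise, which is what makes
the chance-level calibration and familywise type-I tests meaningful.
Fixing one arrangement for a whole sample (as a real single-design
study does) is supported via `randomize_order=False`, but group
inference on raw accuracies is then only valid through the permutation
null, which shares the bias.

## Forward model (synthetic data)

Data are generated *post-preprocessing*: all subjects share one voxel
grid; no realignment, normalization or smoothing is modelled.  For
subject *i* and block *b* the signal amplitude in voxel *v* is

    a_ibv = task_amplitude + s_b/2 * [ g_c * p_iv + g_s * z_i * q_v * social_b ]

inside planted regions (0 outside), where `s_b` = +1 for why and −1
for how blocks, `g_c` (= `condition_effect_gain`) scales the
unit-norm condition pattern `p_i = unit(f * p_group + (1-f) *
p_subject)` with `f = shared_fraction`, and `g_s`
(= `score_encoding_gain`) scales a group-level unit-norm encoding
pattern `q` by the subject's within-sample z-scored behavioral score.
The encoding enters only social-target blocks, so nonsocial contrasts
are a true negative control.  The time series is the design's
HRF-convolved block regressors times these amplitudes, plus a 100-unit
baseline, i.i.d. Gaussian noise (`noise_sd`, default 1), optional
AR(1) temporal correlation and optional low-order polynomial drift.
Motion is a slow random walk with step-displacement spikes (default 2
per run, 1 mm).

**Calibration of gains.**  Effect sizes in pattern space are not
identifiable from published group statistics, so the defaults are
calibrated once against the reported operating range: `g_c = 0.4`
puts ROI decoding of 216-voxel planted regions at ≈68% mean accuracy
(inside the reported 60–82% band), and `g_s = 0.1` yields LOPO ν-SVR
prediction accuracies around r ≈ 0.6–0.8 at n = 50 with ≥80%
permutation-test power.  These are calibration targets for the
*pipeline's* operating range, not a claim about the real data's
generative process.

**Behavior.**  Scores come from a Gaussian copula: network size (SNI)
is lognormal (mean 16.68, SD 10.23), rounded to a non-negative count;
autism-trait scores are rounded normals with group-specific moments
(e.g. 15.55 ± 2.73); IQ is independent normal (108 ± 10).  The latent
trait–SNI correlation defaults to 0.16 (weak, matching the observed
non-significant association).

## GLM

Each block gets its own boxcar regressor spanning first-stimulus onset
to last-image offset, convolved with the canonical double-gamma HRF
(peak delay 6 s, undershoot delay 16 s, unit dispersions, undershoot
ratio 1/6; unit peak) on a 10× oversampled grid.  High-pass filtering
is a cosine (DCT) drift basis up to the 1/100 Hz cutoff, kept as
regressors so estimation stays a single (weighted) least-squares
problem.  Six motion columns (demeaned) and one indicator column per
spike frame are nuisance regressors.

Robust weighted least squares: timepoint weights are the inverse of
the per-timepoint residual variance pooled across voxels, corrected
for leverage (E[r_t²] = (1−h_tt)σ_t², so raw squared residuals are
divided by 1−h_tt before inversion — without this, high-leverage
timepoints are systematically over-weighted and robust estimates
diverge from OLS even on homoscedastic data).  Two reweighting
iterations by default, stopping early when the maximum weight change
falls below 1e-6.  The exact internals of the published robust-WLS
tool are not specified; this variant is documented here and reduces to
OLS via `robust=False`.

The social contrast weights average all why-face and why-hand block
betas minus all how-face and how-hand block betas (weights sum to
zero); the nonsocial contrast is the analogue on nonsocial blocks.

## Decoding

`decode_patterns` trains a linear SVM with fixed cost c = 1 (libsvm —
the same solver family as the published analysis) per
cross-validation fold.  Folds hold out exactly one why and one how
block; all ordered why × how pairs are enumerated (16 folds for 4+4),
a deterministic, unbiased realization of "repeated several times with
different held-out blocks".  No within-fold feature scaling is applied
(betas are used as estimated); accuracy is invariant to a common
affine rescaling of the patterns anyway.

The searchlight evaluates the same classifier on a sphere of
integer-offset voxels (radius 4 → 257 offsets; center-to-center
distance in voxel units; spheres are clipped at mask and grid edges).
Implementation: sphere Gram matrices for *all* centers are accumulated
by FFT convolution of voxelwise pattern products with the spherical
footprint, and all spheres' (and all folds') SVM duals are solved
simultaneously by a vectorized pairwise-SMO solver with a
libsvm-style bias rule (free-SV average, else midpoint of the KKT
interval; SMO tolerance 1e-5 on the step size).  Per-voxel decisions
match sklearn's `SVC` exactly up to ties at zero decision value; the
test suite asserts this agreement, and the tiny raw-libsvm fast path
used in permutation loops is likewise asserted equal to the public
`SVC`/`NuSVR` estimators.

Group ROI discovery: per target condition, each in-mask voxel's
subject accuracies are tested against 50% (one-sample, one-sided);
familywise control over voxels uses the max-statistic sign-flip
permutation (default 5000 flips; Bonferroni behind a flag) — an exact
substitute for parametric random-field FWE under exchangeability.
Significant voxels are intersected across targets; 6-connected
components with ≥5 voxels become ROIs, named in order of peak group
accuracy (ties broken by lexicographic peak coordinate).  Accuracies
enter the test untransformed.

Cross-sample decoding stacks all block patterns of one group as the
training set and tests on the other group's patterns, both directions.

## Prediction

`lopo_svr` is leave-one-participant-out linear ν-SVR (libsvm) on ROI
contrast patterns; ν defaults to 0.5 (the common library default — the
published analysis fixes only c = 1), and accuracy is the Pearson
correlation of held-out predictions with observed scores, with
R² = r² reported alongside.  Features are the raw contrast values
(no extra per-subject centering).  Cross-sample prediction z-scores
features (each voxel across a sample's subjects) and labels within
each sample independently — including the test sample — then fits one
model on the pooled rows (59+17+50 = 126 in the published
configuration) and correlates predictions with the held-out group's
scores.  Univariate controls: the ROI-mean contrast (and per-subject
decoding accuracies) correlated with scores, two-tailed parametric p,
FDR across ROIs applied by the caller.

## Inference

Decoding nulls shuffle the block-position labels with the *same*
permutation for every participant (participants must share block and
class counts) and re-run the full CV; SVR nulls shuffle the
score–subject pairing and re-run the full LOPO (or cross-sample)
pipeline.  1000 permutations by default.  p = (1 + #{null ≥ obs}) /
(n_perm + 1) (never exactly zero); the decision rule is strict
exceedance of the null's 95th percentile, and Benjamini–Hochberg
(step-up) FDR corrects across the ROI family (Benjamini–Yekutieli
behind a flag).  Group comparisons are pooled-variance two-sample
t tests (Welch behind a flag) with confidence intervals.

## QC

Motion traces are low-pass filtered (zero-phase fifth-order
Butterworth, 0.2 Hz) before framewise displacement is computed
(FD = Σ|Δtranslation| + 50 mm × Σ|Δrotation|; first frame 0).
Participant exclusion clusters the (FD p50, FD p95) pairs with DBSCAN
(eps = 1.5 × median distance to the min_samples-th nearest neighbour,
min_samples = 4; both configurable) and flags everyone outside the
largest cluster.  Spike regressors use the separate thresholds
(summed |Δtranslation| > 0.5 mm, summed |Δrotation| > 0.5°, raw DVARS
> mean + 2.5 SD per run).  Behavioral summaries drop no-response
trials from the accuracy denominator, trim RTs beyond 3 SD of the
condition mean, compute d′ with the log-linear (add 0.5 / add 1)
correction, and offer a Box–Cox transform (λ by maximum likelihood)
for skewed accuracy distributions.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run the full chain at
desk scale: chance calibration uses 300 signal-free 12-subject studies
with a 1000-voxel ROI; permutation type-I control uses 200 studies
(n = 30 subjects, 216-voxel ROI, 200 permutations each); ROI recovery
uses 20 subjects on a 24³ grid with a spherical brain mask and
searchlight radius 2 (radius scaled with the grid: a radius-4 sphere
spans a large fraction of a 6³ planted region at this scale, while the
default radius 4 matches whole-brain grids); familywise null control
uses 20 discovery runs at 16³; prediction power/specificity uses 20
studies of 50 subjects with the three-target design.

## What the synthetic validation does and does not show

The generator reproduces the statistical *structure* the pipeline
assumes — block-locked HRF responses, voxelwise Gaussian noise,
partially shared multivoxel codes, a linear score encoding — so
passing tests demonstrate calibration (nulls behave as claimed) and
recovery (planted effects of plausible size are found).  It does not
emulate physiological noise spectra, spatial autocorrelation from
smoothing, susceptibility artifacts, or nonlinear score–pattern
relationships; absolute accuracies and prediction r values on real
data depend on those factors and on preprocessing choices that are out
of scope here.  Published effect sizes from real cohorts are therefore
not reproduction targets; the self-contained calibration quantities
(chance level, cutoff percentile) are.

## Known limitations

- Single-run designs only; no session/run factor in the GLM.
- The robust-WLS variant is one reasonable reading of the named
  algorithm, not a re-implementation of its exact internals.
- Permutation FWE replaces random-field-theory FWE for ROI discovery.
- DBSCAN hyperparameters for motion exclusion are heuristics; with
  very small samples density estimation is refused (< 5 subjects).
- `null_decoding` requires equal block and class counts across
  participants.
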