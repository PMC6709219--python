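# Methods

This note documents the models, conventions, and numerical choices
behind `itpcdecode`, and what the synthetic-data experiments do and do
not establish.

## Signal model and the ITPC statistic

All containers hold trial-resolved arrays `(trials × locations ×
times)` with a uniform ms time axis. After band-pass filtering and
Hilbert transformation, the complex analytic signal's angle is
instantaneous phase. Intertrial phase coherence at a location/timepoint
is the resultant length of the per-trial unit phasors,

    ITPC = | (1/n) Σ_r exp(i k_r) | ∈ [0, 1],

computed per stimulus condition. The statistic is invariant to
per-trial positive amplitude scaling and to any common phase rotation;
trials with an exactly zero complex value (undefined phase) are
excluded at that point with the count adjusted and the exclusion
logged. Under uniform phases E[ITPC²] = 1/n, so the small-sample null
level is ≈ √π/(2√n), not 0 — calibration checks compare against the
finite-n behavior, not the asymptote.

## Frequency bands and filtering

Five fixed bands: α 8–12, β 13–30, γ-low 30–45, γ-medium 55–70,
γ-high 70–90 Hz. The band-pass is a Hamming-window linear-phase FIR
with cutoffs at the band edges and transition width 15% of the lower
edge, applied with its group delay compensated (zero net phase shift —
essential for phase statistics). The evoked (trial-mean) component is
not subtracted before filtering: stimulus-locked alignment is the
quantity of interest.

Narrow bands need filters longer than a 1-s epoch (α at 500 Hz:
~1375 taps). Both the filter and the Hilbert transform therefore
operate on reflection-padded copies trimmed back to the original
length. Consequences, measured in the test suite: in-band amplitude
and phase are faithful to ~2%; out-of-band suppression reaches the
designed stopband (<0.1%) only for samples at least half a filter
length from an epoch edge, and is bounded by a few percent of an
out-of-band tone's amplitude inside short epochs. The first/last 50 ms
are flagged on the analytic container (`edge_ms`) as
edge-contaminated; analyses here keep their baselines and effects away
from epoch edges.

The 10-ms rolling mean used to smooth feature maps is centered, with
the sample count forced odd (5 samples at 500 Hz) and shrinking
windows at the series edges, so no latency shift is introduced.

## LCMV beamformer

The spatial filter for a source with oriented gain `l = L·η` is the
unit-gain minimum-variance solution `w = (lᵀC⁻¹l)⁻¹ lᵀC⁻¹`, where C is
the sensor covariance pooled over **all trials and timepoints** of the
real band-passed data, mean-removed per channel and **not
regularized**. Possible rank deficiency is handled by Moore–Penrose
pseudo-inversion with a relative singular-value cutoff of 1e-10; the
effective rank is logged. The orientation η maximizes unit-gain output
power — the eigenvector of the smallest eigenvalue of `LᵀC⁻¹L` (3×3).
Conventions: a singular 3×3 problem falls back to the largest-gain
axis with a warning; an isotropic tie returns the
lexicographically-first coordinate axis; signs are fixed so the
largest-magnitude component (of η, and of w after orientation) is
positive — sign is unidentifiable and ITPC is unaffected because the
fixed filter applies the same rotation to every trial.

The NAI (neural activity index) normalization divides source power by
projected white-noise power; the noise level is taken as the smallest
nonzero covariance eigenvalue (the standard convention when no noise
recording exists; configurable via the `nai` flag of `apply_filter`).
The scaling is real and positive and therefore transparent to ITPC.
The covariance comes from the real band-passed data and the filter is
applied to the complex analytic data, in that order. The YAML runner
operates on source-space (or simulated) locations directly — with
synthetic subjects sharing one grid, morphing to a common surface is
the identity; the beamformer is a library stage for sensor-space data
with a lead field.

## Decoding pipeline

Rows of the decoding dataset are (subject × condition) cells: each
subject's per-condition ITPC map contributes one sample, so a 17-subject
lexical contrast (3 word conditions : 1 pseudoword) has 68 rows at
ratio 3:1, and 1:1 contrasts have 34. Per timepoint, inside stratified
5-fold cross-validation (fold assignment seeded once per dataset and
reused across timepoints):

1. z-scoring with training-fold statistics (population SD; zero-
   variance features map to 0);
2. feature selection by cross-validated Lasso on ±1-coded labels:
   4 stratified inner folds over a descending logarithmic penalty path
   (default 25 values from the data-derived α_max down to 1e-2·α_max;
   the floor suits the p ≈ n regime where a near-zero penalty is
   degenerate). Validation-MSE ties resolve toward the larger (sparser)
   penalty. An empty selection falls back to the single
   largest-|coefficient| feature at the densest penalty, keeping the
   pipeline total;
3. logistic regression (C = 1, l2, unpenalized intercept) on the
   selected features; held-out scoring by ROC-AUC of the continuous
   decision values (ties count ½, exactly the pairwise probability).

Stratified folds are built by dealing each class's shuffled rows
round-robin, so every fold's class ratio matches the dataset within
rounding. Under label permutation with the reused fold assignment a
fold can end single-class; such folds score NaN and drop out of the
fold mean (a permutation with no scoreable fold counts as chance).

**Engines.** The permutation test refits this pipeline m × gated-
timepoints times, which makes per-call overhead of general-purpose
estimators the binding cost on one CPU. The two model fits are
therefore available from two interchangeable backends: `"fast"`
(default), compact numba kernels — Gram-based coordinate descent over
the penalty path and damped Newton for the logistic — and
`"sklearn"`, the same numerics through `lasso_path` and
`LogisticRegression`. Both optimize identical objectives on identical
grids; the suite holds selected masks identical and logistic weights
equal to ~1e-6 on random draws, and full AUC curves equal within
rounding noise.

**Patterns.** For a linear decoder s = Xw the Haufe activation pattern
is `a = Cov(X)·w / Var(s)`, computed per fold on the standardized
training matrix. Cluster localization reports the fold/timepoint mean
pattern with top/bottom-5% masks on the mean, plus the union of the
per-fit 5% masks. The union is the right object for recovery checks:
a single 5% mask is too small by construction to overlap a broader
true-effect set (5% vs 25% of locations caps Jaccard at 0.2), whereas
the pooled union grows toward the effect's true extent.

## Significance testing

Per band, the gate threshold is `mean + 1.5·SD` (population SD) of the
observed mean-AUC curve over the baseline window (default: all
timepoints before the divergence point). Only post-DP timepoints above
the threshold are permuted: labels are shuffled (across all rows by
default; a within-subject option exists) and the complete pipeline is
rerun m = 2000 times (reduced in desk-scale experiments), reusing the
observed fold assignment (re-stratification per permutation is a
config option). `p = (b+1)/(m+1)` with b the number of permutations
scoring ≥ the observed value, so p ≥ 1/(m+1) and larger observed
scores never increase p. Significant runs must span ≥ 10 ms
(end − start, boundary inclusive) to survive; cluster tables report
peak score and fold SD at the peak, peak/start/end times relative to
the DP, length, the time-average of the mean curve, and the SD across
folds of the cluster-mean score, all scores in percent.

Note on "chance" for unbalanced contrasts: ROC-AUC has null
expectation 0.5 regardless of the 3:1 class ratio (accuracy would sit
at 75%). The package asserts neither; inference is always against the
empirically computed permutation null, whose mean the experiments
report.

## Synthetic data

The generator emulates the study structure the pipeline targets:
17 subjects, stimulus conditions × 100 repetitions, 500-Hz epochs from
−100 to 900 ms, divergence points at 300 ms (lexical/semantic) and
408 ms (morphosyntax), ratios 3:1 (lexical) and 1:1 (semantic/syntax)
via the contrast presets. Effects are windowed sinusoidal carriers:
per trial the phase **at window onset** is drawn von Mises(0, κ_class)
— κ = 0 uniform (null), larger κ increasingly stimulus-locked, with
E[ITPC] → I₁(κ)/I₀(κ) — and the carrier then evolves deterministically
at its frequency through the window, modeling phase resetting at a
divergence point. Elsewhere the data is Gaussian noise, white by
default so band-limited null phases are exactly uniform (a 1/f option
exists). Per-subject κ jitter is multiplicative log-normal
(`between_subject_sd`), leaving effect timing sharp across subjects.
All randomness descends from one integer seed via
`SeedSequence(seed, spawn_key=(subject_index,))`.

Unstated magnitudes are package choices, fixed once: carrier amplitude
1; effect contrast κ = 0 vs 4 (expected ITPC ≈ 0.86 vs null);
`noise_sd_for_band_snr` sets the white-noise SD so in-band noise power
equals carrier power (0 dB); between-subject κ jitter SD 0.2 in effect
experiments.

What the simulations do **not** emulate: realistic head geometry or
anatomy (the toy lead field is a random smooth 1/r² geometry), 1/f
background spectra and oscillatory bursts, artifacts, inter-subject
spatial misalignment (morphing is identity), or correlated sources.
Passing tests therefore establish the statistical machinery —
calibration, recovery, localization under the stated model — not
performance on real recordings.

## Desk-scale experiment sizes

The validation experiments run the full study logic at reduced size,
chosen to keep a complete run on one CPU in minutes while preserving
the prescribed design constants (17 subjects, α = 0.05, 1.5-SD gate,
10-ms rule, m = 200 permutations where reduced):

- **Type-I calibration:** 200 no-effect simulations, 1:1 contrast,
  17 subjects × 20 trials/condition, 8 locations, 250 Hz, −100..100 ms
  epochs; the per-timepoint rejection rate is measured at two
  designated ungated post-DP timepoints per simulation (400 tests) and
  the family-wise rate from the fully gated cluster pipeline.
- **Effect recovery:** 16 locations with the effect in 4 (25%),
  window 100–150 ms post-DP in γ-low (carrier 40 Hz), 50
  trials/condition, 0 dB band SNR, κ jitter 0.2; decoding every
  2nd sample (8-ms steps), penalty path of 10 values.
- Feature counts are configurable; a full-scale cortical source space
  (thousands of vertices) is a dimensionality choice, not a change of
  the math.

## Known limitations

- The gate makes the procedure conditional: p values exist only where
  the observed curve crossed the threshold, so the reported family-wise
  rate refers to the gate + duration rule jointly.
- Coordinate descent at near-zero penalties on p ≈ n data is
  ill-conditioned; the default path floor (1e-2·α_max) avoids that
  regime, at the cost of never exploring nearly-dense solutions.
- Reflection padding bounds but does not eliminate edge leakage for
  epochs shorter than the band filter; keep baselines and effects away
  from epoch edges, or record longer epochs.
- The permutation engine reuses the observed fold assignment by
  default; with very few rows, shuffles can leave folds single-class
  (handled as described above), slightly reducing the effective number
  of folds for those permutations.
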