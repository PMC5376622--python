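# Methods

## Stimulus model

The oscillating disc is modeled at the frame level (60 Hz). The nominal
parameters — 2.30° of rotation per frame over a 60° sweep, a 5-frame
(~83 ms) stationary pause at each reversal, two reversals per second — are
mutually inconsistent by one frame per half-cycle (round(60/2.30) = 26 moving
frames + 5 paused = 31 frames, against the 30-frame half-cycle implied by two
reversals per second). The reversal rate is treated as the governing
constraint, since flash timing (exactly one flash per second in the
motion-shift conditions) hangs off it: each half-cycle is 30 frames, 25
moving (57.5° traversed) plus the 5-frame pause, after an initial partial
sweep of ~45° that aligns subsequent pauses with the 1-s grid.
`nominal_sweep_frames` still exposes the 26-frame value implied by step and
extent. Physical-shift conditions flash at 2 Hz with no motion; motion-alone
and fixation never flash. The starting direction of motion is a seedable
per-run random choice.

Psychophysics: each participant's effect size per direction is the arithmetic
mean of three adjustment settings; effects are stored signed (CLW positive)
and compared between directions by a two-tailed paired t-test on magnitudes.
The matched physical shift used downstream is the direction-averaged
magnitude.

## GLM

Per-voxel OLS on the concatenated session: six condition regressors
(12-s boxcars convolved with a peak-normalized double-gamma HRF, peak 5 s,
undershoot 15 s, 1:6 undershoot ratio, unit sustained response so betas are
in signal units), four Legendre polynomials per run (orthogonal within run;
same span as raw polynomials), and six motion regressors across runs.
Fixation is modeled explicitly, as the design prescribes; because blocks tile
the run, the sum of condition regressors is nearly collinear with the run
constants. This is deliberate and benign: the SVD-based solver handles it,
and every analysis contrast is a condition difference, orthogonal to the
ill-conditioned mean direction (the realized condition number is ~20 thanks
to HRF onset/offset ramps at run boundaries).

Serial autocorrelation is not modeled: only betas — not their variances —
enter the correlation analysis, so plain OLS suffices; an AR(1) prewhitening
flag (`fit_glm(..., ar1_rho=...)`) exists for sensitivity checks, and the
generator can produce AR(1) noise to exercise it.

Censoring: backward difference of the six motion parameters within run (zero
at run starts, so between-run shifts are ignored); where the Euclidean norm
strictly exceeds 0.3, that TR and the one before are dropped by row deletion.

Voxel selection: one-tailed t for (CLW-S + CCW-S)/2 > F, thresholded at
α = 0.01 Bonferroni-corrected by the number of voxels in the union of all
analyzed ROIs (the natural test family; the correction denominator is
configurable). One-tailed because the criterion is a *larger* response than
fixation. Residuals at numerical round-off level are clamped to zero
variance so exact fits flag infinite t rather than astronomically large
finite values.

## MVPA statistic

Difference maps CLW-M − CCW-M and CLW-S − CCW-S over the selected voxels;
Pearson r across voxels; Fisher z′ = atanh r for all aggregation.
Correlations over fewer than 3 voxels, or with zero variance in either map,
are flagged invalid and excluded from aggregation rather than propagated as
NaN. |r| ≥ 1 is clamped to 1 − 1e−12 with a warning.

## Inference

Per participant, the CLW-M/CCW-M block labels are reshuffled *within each
run* (preserving the 7/7 balance; the exchange unit is a design choice — the
block labeling is the only randomized element of the design, and within-run
exchange preserves run structure), the GLM is refit with identical censoring
and nuisance regressors, and the new motion difference map is correlated
against the *observed* physical-shift map; 1000 shuffles form the null.
Voxel selection involves no shuffled labels and is computed once from the
unshuffled data. The per-participant p is the raw exceedance proportion
(an add-one-smoothed variant is available by flag). Because only the
assignment of blocks to the two motion columns changes, the refit is solved
exactly by the Frisch–Waugh–Lovell shortcut — project the per-block
regressors and data onto the complement of the fixed columns once, then a
2×2 solve per shuffle; a literal full-refit path is retained and asserted
equal in the tests. Exhaustive enumeration of all within-run labelings is
available for small designs and anchors the Monte-Carlo p in the tests.

Group level: (1) bootstrap — draw one null z′ per participant, subtract from
the observed z′, average across participants, repeat 1000 times; p is the
fraction of mean differences below zero; (2) a one-tailed paired t-test of
observed z′ against each participant's null mean (one-tailed because the
hypothesis is directional: positive correlation). All-zero differences give
t = 0, p = 0.5; nonzero constant differences raise as degenerate.

## Controls

Random clusters grow a Euclidean sphere (voxel units) around a uniformly
drawn seed inside the shared gray-matter mask (voxels present in ≥4
individual masks), excluding the analyzed ROIs, trimming the outermost shell
at random to the exact target count. Matched-count mode matches the average
number of *selected* V1-like voxels; matched-size mode matches the ROI's
total size and applies the same Bonferroni selection within each cluster
(corrected by the cluster size), dropping participants with ≤2 surviving
voxels and clusters valid in fewer than 4 participants.

Confound correlations pair each ROI's observed z′ with a per-ROI metric
(mean SNR t of all-stimulus > fixation, selected-voxel count, total ROI
size, mean |t| of CLW-S > CCW-S) and shuffle the metric among ROIs within
participant 1000 times. Both tail conventions are reported: `p_lower`
(fraction of shuffled correlations below the observed, the convention as
stated) and `p_greater` (upper tail — the significance of a positive
confound correlation, which is what the reported numbers correspond to).

Split-half validation selects voxels on odd runs at corrected p < 0.05
(relaxed from 0.01 to offset the halved data), correlates on even runs, and
vice versa; overlap is the fraction of full-data-selected voxels recovered,
and two-tailed paired t-tests compare full-data z′ with each half-based z′.
A no-selection variant reruns correlation and both group tests on all ROI
voxels.

Effect size: ratio = MAD(dM)/MAD(dS) (MAD = mean absolute deviation from
zero), converted to degrees by each participant's matched physical shift —
the direction-averaged magnitude, since the original conversion rule is
unstated; per-direction shifts are also available. Under the Gaussian
generative model E[MAD]² = (2/π)·variance, so the raw ratio tends to
√(κ²σ_P² + σ_η² + σ_em²)/√(σ_P² + σ_es²) (`expected_mad_ratio`): it is
positively biased at κ = 0, which the tests assert and quantify.
`debiased_mad_ratio` removes the measurement terms using GLM standard
errors and recovers κ without material bias.

## Synthetic data

The generator reproduces the study design exactly: 7 participants × 10 runs
× 184 TRs (TR 2 s); per run, 30 randomly interleaved 12-s blocks (CLW-M and
CCW-M seven repetitions, the other four conditions four each) plus 2
fixation TRs at each end. Ground truth per participant: a zero-mean
physical-shift pattern Pᵥ ~ N(0, σ_P²) (σ_P = 1 beta unit), motion pattern
κᵥPᵥ + ηᵥ with η ~ N(0, 0.15²), and response amplitudes ampᵥ ~ Exp(1)
shared by all stimulus conditions so responsive voxels exceed fixation.
Defaults: κ = 0.2 for the V1-like ROI (the ~20% perceptual/physical regime),
κ = 0 for the control ROI; both 264 voxels on a 12³ grid. BOLD time series
add the HRF-convolved block responses (through the same design constructor
the GLM uses, so noiseless simulations refit exactly), per-run cubic
Legendre drift, a motion-coupled nuisance, and i.i.d. Gaussian noise
(optionally AR(1)). Motion parameters follow a random walk (step sd 0.02)
with fresh per-run offsets and permanent spike steps of 0.6 at rate
0.055/TR — each spike exceeds the 0.3 censoring threshold by construction,
and the resulting ~11% censored TRs and, with noise_sd = 2.4, the ~45%
selection retention match the regime the analysis is designed for. The
`noise_sd`/amplitude pairing was set once from the targeted retention band
(40–50%) and the per-beta standard errors it implies; `small_config` scales
`noise_sd` to 0.8 so the shorter test sessions keep the same per-beta
standard error regime. Adjustment-task data: participant means
~ N(12.5°, 3²), direction asymmetry sd 1°, within-condition setting sd 1.5°,
initial offsets uniform in ±20°.

What the generator does *not* emulate: spatial noise correlation and
smoothness, physiological noise, the coupling of pattern strength to
responsiveness (Pᵥ is independent of ampᵥ, so voxel selection does not
increase the observed correlation the way it does in real data — the
no-selection variant can even come out slightly higher here), retinotopic
map structure, and between-participant anatomical variability beyond random
gray-matter masks. Passing tests therefore validate the estimator and its
calibration under the stated statistical structure, not robustness to real
fMRI artifacts.

## Problem sizes and determinism

The test suite runs reduced designs (2 runs × 88 TRs, 6³ grids, 30–40-voxel
ROIs, 200 permutations) chosen to keep per-beta standard errors in the
full-size regime; calibration tests use 100 simulated participants /
100 null datasets, and the specificity test 200 clusters.
`scripts/acceptance.py` runs the full-size study (1000 permutations, 1000
bootstrap draws, 1500 clusters). Every random stream descends from one
master seed via named `SeedSequence` children (per participant, per stage),
so identical configuration and seed reproduce reports byte for byte.

## Known limitations

Plain OLS leaves serial autocorrelation in the residual variance estimates;
contrast t maps used for selection are therefore mildly optimistic under
AR(1) noise (the betas feeding the correlation are unaffected). The
bootstrap group test is approximate for n = 7 participants (its null
rejection rate is verified by simulation, not exact). Printed-precision
checks of t-to-p conversions reproduce published roundings except where the
published pair is internally inconsistent (t = 2.00 with a one-tailed
p = 0.0443 implies an unrounded t; the pipeline reports exact values).
Real-data ingestion expects voxel-index space (0-based, x/y/z/t NIfTI
order); no smoothing, resampling, slice-timing or spatial normalization is
performed — masks and ROI labels must already be aligned to the functional
grid.
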