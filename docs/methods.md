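# Methods

This note documents the models, parameters and numerical choices behind
`pcsacc`, and what the synthetic-data tests do and do not establish about
real recordings.

## Task model

A session is a sequence of trials. Each trial: fixation-point onset (trial
onset) → instruction period of duration U(0.3, 0.5) s → target onset
(instruction offset) in one of 8 directions (45° steps) → go cue 100 ms
later → response window of 500 ms. Within each block all 16
(direction × condition) configurations appear once in random order. A trial
is correct when the first post-go saccade lands within 6° of the goal (the
target for prosaccades, its mirror for antisaccades) and gaze stays there
for 100 ms; saccades with RT < 100 ms are excluded as anticipatory, and
saccades launched after the 500 ms deadline are timeout errors. The
intertrial interval is 1.5 s (a configurable choice — the source study does
not report it), long enough that the intertrial baseline window (400–50 ms
before trial onset) never overlaps the previous trial. Reward timing is not
modelled.

## Synthetic kinematics

Eye traces are fixation plus minimum-jerk saccades with Gaussian positional
noise (default SD 0.03° per axis at 350 Hz, a typical video-oculography
noise floor). Amplitude A and duration D are drawn per trial; peak velocity
is *emergent* through the minimum-jerk relation V_p = (15/8)·A/D and is
never drawn.

Three calibration details matter:

1. **Moment-matched floored normals.** Published summary statistics of
   included trials describe the distribution *after* the anticipatory-trial
   exclusion, i.e. a left-truncated distribution. Each kinematic draw is a
   normal truncated at a physical floor (RT 0.1 s, amplitude 2°, duration
   10 ms) whose parent (μ, σ) is solved numerically (scipy `truncnorm`
   moment inversion) so that the floored draw has exactly the target
   mean/SD. Drawing from a plain normal with the target moments and then
   flooring would bias the included-trial mean upward by σ·φ(α)/(1−Φ(α))
   (≈ +17.5 ms for the prosaccade RT distribution); moment matching absorbs
   this truncation bias by construction, which is why the recovered means in
   `scripts/acceptance.py` sit on the published values rather than above
   them.
2. **Main-sequence coupling.** A and D are drawn jointly from a correlated
   Gaussian (floors enforced by rejection). With independent draws, Jensen's
   inequality on E[A/D] inflates the mean emergent peak velocity by ≈ +7%
   (pro) to +19% (anti) relative to the ratio of means; real saccades obey
   the main sequence (longer saccades last longer), which suppresses this.
   The default correlations (pro 0.32, anti 0.68) were calibrated once so
   that the mean peak velocity measured through the noiseless filter chain
   reproduces the published per-condition means.
3. **Residual measurement bias.** With default noise, the full chain reports
   peak velocities ≈ 1–3% high (noise adds in quadrature near the peak) and
   reaction times ≈ 2–5 ms late (the onset is refined to a low-threshold
   crossing on the smoothed trace). Both are properties of the measurement,
   not the generator, and are well within the sampling tolerances used in
   the acceptance checks.

## Filter chain and detection

Position is low-pass filtered (31-tap FIR, 70 Hz cutoff, zero-phase) and
Savitzky–Golay smoothed (20 ms window, order 4); velocity is the SG
derivative, speed its Euclidean norm; acceleration differentiates speed and
is median-filtered (3 samples). The cutoff, order and SG-derivative choices
were fixed by requiring that the peak speed of a noiseless minimum-jerk
saccade of 10°/40 ms survive within 1% of the analytic 1.875·A/D at 350 Hz;
a 50 Hz cutoff with quadratic SG and central differences loses 2–4% and was
rejected.

Detection thresholds are adaptive: high = mean + 6 SD and low =
max(mean + 1 SD, 5% of the event's peak speed) of the session's pooled
fixation-speed distribution. Since speed is a non-negative magnitude, its
noise distribution has a positive mean; offsetting both thresholds by the
mean keeps the multipliers scaling the SD as intended. Supra-threshold
epochs closer than 10 ms are merged, epochs shorter than 10 ms discarded,
and onset/offset are the sub-sample-interpolated low-threshold crossings.
The peak-relative component of the low threshold keeps timing errors
roughly size-independent: on noiseless saccades the mean absolute
onset/offset error is < 1 sample at 350 Hz (worst case ≈ 2.5 samples for
the slowest saccades — irreducible under 20 ms smoothing).

## Spike model and SDF

Spike trains are inhomogeneous Poisson on a 1 ms rate grid. SS profiles:
boxcar facilitation/suppression over the instruction period, a Gaussian
transient (SD 50 ms, configurable) at saccade onset + latency, a linear ramp
from instruction onset to saccade onset, and a multiplicative pro-trial
condition gain; rates clip at zero. CS trains run at ~1 Hz with boxcar gains
in the instruction (50–350 ms after instruction onset) and saccade
(±150 ms) windows. Every CS deletes SS spikes for the following 15 ms
(climbing-fiber pause). All randomness descends from one session seed via
`SeedSequence` spawning (child 0 schedule, child 1 eye, children 2+ cells),
so equal seeds give byte-identical serialized sessions.

The SDF is a sum of unit-mass Gaussians evaluated on a 1 ms grid, kernel
support truncated at ±8σ, no edge renormalization (a spike near a window
edge contributes less than unit mass inside the window — documented, not
corrected). The pause check uses the CS-triggered SS cross-correlogram
(1 ms bins, lags 0–50 ms, first 120 s, ≥ 10 CS required) and declares a
pause when ≥ 8 consecutive ms stay below 50% of the pre-CS rate; the "short
pause" length is never quantified in the source analysis, so the 8 ms / 50%
rule is a package decision. Cells failing the check are flagged but retained
for SS analyses.

## Classification statistics

All windows are half-open [a, b). Baseline: [−0.400, −0.050) s before trial
onset (inside the intertrial interval). Saccade-relatedness compares
baseline vs [0, 0.150) s post saccade-onset *rates* (the windows differ in
length) per direction with a rank-sum test, uncorrected across the 8
directions as in the source analysis; a flat cell is therefore flagged at
the multiplicity-driven rate 1 − 0.95⁸ ≈ 0.34 (empirically ≈ 0.38 at 20
trials/direction — small-sample p-value discreteness pushes the rate
slightly around the nominal value; at 5 trials/direction it drops to
≈ 0.24). A Benjamini–Hochberg switch exists but is off by default.

Epoch classes use paired signed-rank tests: instruction = mean rate in
[−0.400, 0) before instruction onset vs the last 300 ms of the instruction
period; saccade = [−0.150, 0) vs [0, 0.150) around saccade onset. Ramping
fits OLS to the trial-averaged SDF over the last 300 ms of instruction;
ramping iff R² > 0.75. **Caveat:** because the 50 ms kernel leaves only
~1.7 independent samples per 300 ms, the SDF noise is strongly
autocorrelated and the R²-only rule flags ~13% of flat cells regardless of
trial count; no pure R² threshold on a 50 ms-smoothed SDF can reach a 1%
false-positive rate. The rule is implemented as stated; users wanting a
calibrated ramping test should additionally require slope significance on
coarse independent bins.

The pro/anti condition test is a two-sample K-S on per-trial saccade-window
spike counts. Counts are kernel-weighted (each spike contributes its
Gaussian-kernel mass inside the window, consistent with every other rate
estimate here) and the classical asymptotic K-S null is used: on tied
integer counts the exact-method K-S is severely conservative (measured
type-I ≈ 0.3% instead of 5%), while the kernel-weighted asymptotic version
measures ≈ 5.5% on null cells.

## Complex spikes and reciprocity

CS analyses use a 25 ms kernel (CS are sparse; 50 ms over-smooths the
±150 ms windows). Epoch modulation compares the trial-averaged CS SDF in
the epoch window against mean ± 3 SD of the intertrial baseline (500 ms
before trial onset). The baseline SD is the *standard error of the trial
average*, estimated from the across-trial variance of per-trial SDFs:
estimating it along time from the 500 ms trial-averaged segment (~7
kernel-independent samples) under-resolves the SD and inflated the
false-positive rate of the ±3 SD rule to ~22%; with the across-trial
estimate the measured null rate is < 10%.

Reciprocity: ΔCS is the signed largest-magnitude deviation of the CS SDF
from its baseline within the epoch window; ΔSS is the signed
largest-magnitude SS-SDF deviation from the SS intertrial baseline within
±150 ms of the CS peak (the intertrial baseline is used for ΔSS too — a
config-documented choice; a pre-epoch baseline is arguable). The product
ΔCS × ΔSS is negative exactly when the modulations are opposite-signed. The
instruction-vs-saccade regression applies exactly one Cook's-distance
exclusion pass (> 3 × mean, then one refit); iterating the exclusion
changes results and is deliberately not done. Note that the null
distribution of R² for n = 16 independent products is Beta(1/2, 7) —
P(R² < 0.15) = 0.86 at most, ≈ 0.74 after the exclusion pass — so small
null samples produce R² above 0.15 more often than intuition suggests.

## Demixed PCA

The PSTH tensor is (neuron, condition, time), 100 ms bins aligned to
instruction offset (default window −0.5 to +1.0 s), trial-averaged over
correct trials with directions pooled; neurons need ≥ 5 trials per
condition. After per-neuron mean-centering, exactly two marginalizations
are formed (this is a two-condition, correct-trials-only design — no
decision or interaction marginalization): the condition average
(condition-independent) and the residual (stimulus). Per marginalization,
the ridge-regularized reduced-rank regression
B = X_m Xᵀ (X Xᵀ + λ·tr(XXᵀ)/N·I)⁻¹ followed by an SVD of BX yields
encoder axes F (top left singular vectors) and decoders D = FᵀB; component
variance fractions are the squared singular values over the total centered
tensor variance, so ordering is automatic and, in the single-marginalization
λ = 0 limit, the axes coincide with PCA eigenvectors (tested against a
brute-force eigendecomposition to < 1e-6 subspace angle). λ defaults to 0
for determinism; `lam=None` selects it on a log grid by held-out-trial
cross-validation.

Decoding: per time bin, a held-out pseudo-trial per neuron and condition is
classified by the nearest class mean of its projection on each stimulus
axis (chance 0.5), averaged over 100 held-out draws. Significance uses a
shuffle null — condition labels permuted within neuron, 100 shuffles — with
a max-over-time 95th-percentile threshold per component. On null data the
*time-averaged* accuracy sits in [0.45, 0.55], but individual bins fluctuate
persistently by up to ±0.2 because the training class means barely change
across held-out draws; this is precisely why the max-statistic shuffle
threshold, not a per-bin band, is the significance criterion. All reported
components are ranked by decoding accuracy rather than hand-selected.

## What the synthetic tests do not show

The generator produces Poisson spiking, stationary baselines, noise-free
task compliance (no blinks, drifts, or microsaccades), unimodal
minimum-jerk saccades, and independent cells. Passing tests therefore
establish the correctness and calibration of the *pipeline*, not the
physiology: real SS trains are non-Poisson (CV < 1), real sessions drift,
real populations are correlated, and the published group means, dPCA
variance percentages and reciprocity R² values are properties of the
unreleased recordings that this package does not attempt to reproduce.
Cohen's d is the pooled-SD definition; printed effect sizes from the source
study are not reproducible from its summary statistics and are not an
acceptance surface.

## Problem sizes

Default test and acceptance problem sizes were chosen as the smallest that
make the statistical assertions stable: 10-block sessions (160 trials, 80
per condition) for classification, 2000 trials per condition for the
kinematic recoveries, 200 cells for label-recovery rates, 1000 cells for
K-S calibration, 16-cell populations (the lateral-region sample size) for
the reciprocity regression, and 40-neuron/60-trial populations for
decoding.
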