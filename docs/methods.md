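# Methods

This note documents the models, numerical choices and limitations behind
the package. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Task geometry and the equivalence contract

All positions are in arbitrary workspace units (au): the screen height
spans 4 au, targets sit on a 2 au-diameter ring at the four cardinal
directions, the target plane is 3 au across, the start point 0.1 au, the
target 0.2 au, the cursor 0.15 au, and the homing snap radius 0.05 au
(strict inequality at the boundary; the choice is irrelevant to every
downstream measure). Screen y increases upward and angles are measured
counter-clockwise from +x.

The defining contract of the Point/Look comparison is that *identical hand
movements acquire a given target in every context*. The camera model is
chosen to make that exact rather than approximate: pan and tilt are each
mapped independently through the pinhole relation `s = d·tan(angle)`, with
the task plane at distance `d` (default 10 au, keeping angles below ~9°
over the workspace — the small-angle regime). Under this parameterization a
camera rotation acts as a rigid screen translation of the task plane, so
the cursor-relative position of every plane point equals its Point-context
counterpart sample by sample, to floating-point precision. A single global
gnomonic projection cannot translate the plane rigidly (perspective
distortion is second order in the angle), so we adopted the per-axis form;
the equivalence contract, which the analysis depends on, takes priority.
The visuomotor rotation is applied to the cursor in Point and to the
camera update in the Look contexts — numerically the same task-plane
cursor path.

Inverted Look negates the input on both axes by default, which makes the
standard 180° hand-angle correction for inverted trials exact; a
vertical-only inversion (the first-person-shooter convention, "forward
looks down") is available via `inverted_axes="vertical_only"`. With the
both-axes convention the 180° correction commutes with sign normalization,
so the order of the two steps is immaterial.

## The synthetic learner

The generator is deliberately the *minimal* process consistent with
canonical adaptation curves; it makes no claims about participants. A
state `x(θ)` is kept at the four cardinal hand directions. Every trial with
movement feedback retains the whole state by `A` and adds
`B·e·exp(−d(θ, θ_plan)²/(2σ²))`, with `e` the negated angular cursor error
(including motor noise) and `θ_plan` the planned hand vector (hand
direction plus current aim) — adaptation generalizes around where the hand
was planned to go, not around the visual target. The state is indexed by
hand direction only, so learning transfers across contexts by
construction; a context-specific variant can be emulated by resetting the
state at a context switch.

Defaults (units, rationale):

| parameter | default | meaning |
|---|---|---|
| `retention_A` | 0.99 /trial | slow decay; washout retains visible after-effects over 25 cycles |
| `learning_rate_B` | 0.08 /trial | with four targets and σ = 45° this yields a ~21–22° asymptote against a 30° rotation and a ~27° asymptote under single-target training — the magnitudes such experiments report |
| `gen_sigma` | 45° | local generalization: ~13% carry-over at 90°, ~0 at 180° |
| `motor_noise_sd` | 4° | typical online-study reach variability |
| `p_jump_start` | 0.05 | fraction of movements launched at an uncued target |
| `glitch_rate` | 0.003 | per-trial single-frame input glitches (a few per thousand) |
| `rt_limit_threshold_ms` | 750 (mouse) | 50%-success time limit; the two staircase starts (450/1050 ms) bracket it symmetrically; trackpads add 330 ms |
| `rt_limit_slope_ms` | 100 | logistic psychometric slope |

Jump starts follow the task logic: where the online take-off check is
active (experiments with trial repetition) the attempt is aborted at the
0.2 au radius and the trial repeats in place, so every scheduled trial
still receives a valid execution and a learning update. Without the online
check the jump start *is* the trial — the movement goes to an uncued
target and no update is applied (the feedback is off-plan), though
retention still acts. An explicit-strategy component is deliberately
omitted (the pipeline measures total learning); the update hook makes an
additive strategy term easy to add.

Trajectories are 1 au minimum-jerk reaches (0.45 s) along the executed
hand direction, followed — when the cursor misses the target by more than
0.05 au — by a late 0.2 s corrective sub-movement that lands the cursor on
the target, reproducing the hooked early-rotation paths. Samples are
emitted at a per-participant frame rate (60/120/144 Hz) with uniform ±10%
per-frame jitter. The cursor channel is produced by the forward mapping of
the context, so recorded data honour the equivalence contract exactly.
Every source of randomness descends from one master seed through a spawned
seed tree; a cohort is fully reproducible from `(config, seed)`.

What the generator does *not* emulate: reaction times, online feedback
corrections during the outward reach (the correction starts after the main
movement), strategy use and its cueing, device-specific kinematics beyond
the staircase starting points, dropped-frame gaps, or upload failures.
Passing tests therefore validate the measurement chain and statistics on
data whose ground truth is known — they do not certify behaviour on real
recordings beyond the features listed above.

## Preprocessing

Stage order is fixed: glitch screening on **raw frames**, then linear
resampling to 100 Hz, then the zero-phase low-pass. The glitch rule flags a
trial when the frame-to-frame speed changes by strictly more than 40 au/s
in either the input or the task-plane cursor channel (the two coincide
under a pure rotation; both are checked because in Look-context recordings
the identity of the logged channel can be ambiguous). Flagged trials are
excluded, not repaired; gaps longer than 200 ms are likewise grounds for
exclusion rather than interpolation.

The filter is a zero-phase 2nd-order Butterworth with a 15 Hz cutoff
(−3 dB per conceptual pass), i.e. a net magnitude of
`|H(f)|² = 1/(1+(f/15)⁴)`. It is applied spectrally: the trial is padded by
odd (rotational) reflection of 24 samples per side, multiplied by the
squared Butterworth magnitude in the frequency domain, and trimmed. A
time-domain bilinear-transform filter run forward-backward has the same
−3 dB point but warps the response toward Nyquist (at 30 Hz it attenuates
to 0.018 rather than the analytic 0.059); the spectral form realises the
stated two-pass magnitude exactly at all frequencies while keeping zero
phase, time-reversal symmetry, unit DC gain and a monotone response.
Trials shorter than the pad length cannot be filtered and are excluded as
too short. Residual edge effects are confined to a few samples at the
trial ends, far from the peak-speed sample used for measurement.

## Kinematics

Peak radial speed is the maximum central-difference derivative of the
distance from the start point, computed on the *input* (hand) channel —
which the perturbation never touches. Hand angle at peak speed is the
signed angle from the start→target line to the start→hand line at that
sample; take-off angle is the same quantity at the first crossing of the
0.2 au radius, with the angle linearly interpolated between the bracketing
samples. First crossing (not last) is used because the point of the
take-off measure is to catch movements early, before feedback can correct
them.

Raw angles are CCW-positive and internal. Reported angles flip sign for
counter-clockwise-perturbation participants so positive always means
"opposite the perturbation"; trials in unperturbed blocks are normalized
with the participant's assigned direction so all of a group's angles share
one convention. Inverted-Look trials get a 180° correction so the angle is
measured from the ideal aim location; the same correction is applied
before jump-start thresholding on those trials (the threshold is symmetric,
so raw-versus-normalized is otherwise immaterial). The offline jump-start
rule (|peak| > 60° **and** |take-off| > 60°) applies where no online check
ran; where trials were repeated online, a residual |peak| > 60° filter
removes the stragglers. Degenerate trials (no displacement at peak, never
crossing the take-off radius, too short to filter) are marked unanalyzable
rather than guessed at.

## Aggregation

Cycles are four consecutive trials (one per target); means use valid
trials only, an all-invalid cycle is missing, and repeated trials replace
their originals in sequence (in-place replacement, so cycle numbering is
stable). Periods are fixed windows: last 10 cycles of (trained) baseline,
first/last 10 cycles of rotation and washout, first 10 cycles of transfer;
the single-target design uses first/last 10 *trials* of its rotation
block. After-effect = early washout − late rotation; transfer = early
transfer − late rotation. Generalization probes are baseline-corrected per
participant/context/target and labelled by the relation of their planned
hand direction to the trained (upward) hand direction: under Inverted Look
the *bottom* screen target is the trained hand direction. Lateral (0°/180°)
probes stay in the table but are excluded from the trained/untrained
contrast. The mean of the last five top-up trials per generalization cycle
is reported as the re-asymptote check. Missing cycles are skipped, never
imputed.

## Statistics

The mixed ANOVA is computed by pingouin's standard mixed-design sums of
squares (the test suite verifies exact agreement with a brute-force
sums-of-squares oracle on balanced designs, and the between-F = t²
degenerate-case identity); partial eta squared follows
`F·df₁/(F·df₁+df₂)`. Marginal-mean contrasts at a within level are
pooled-variance two-sample t tests (df = n−2). Stand-alone comparisons use
Welch (independent) or paired t tests with 95% CIs; degenerate
zero-variance cases are flagged instead of returning NaNs. All tests are
two-tailed at α = 0.05.

Bayes factors are **BIC approximations**, `BF₁₀ = exp((BIC₀−BIC₁)/2)`,
labelled `bf10_approx` throughout: they are a transparent, prior-free
surrogate and are not expected to match default-prior (JZS) values from
dedicated Bayesian packages.

Mixed regressions (random participant intercept) are fitted by REML via
statsmodels. Satterthwaite degrees of freedom are computed from first
principles: for a contrast `c`, `df = 2·f²/(gᵀ·A·g)` with
`f = cᵀ·Cov(β̂)·c`, `g` its finite-difference gradient in the variance
parameters, and `A` the inverse curvature of a closed-form random-intercept
REML log-likelihood evaluated at the fitted variances. Singular fits
(vanishing intercept variance, perfect fits) fall back to a fixed-effects
regression with residual df, flagged via `satterthwaite=False` and a
warning. The intercept's t test can be offset against a reference value
(e.g. an asymptotic-learning level) for transfer-block analyses.

## Problem sizes and calibration checks

The test suite and the acceptance script run everything on synthetic data
at sizes chosen to estimate each quantity stably: 1,000 random input
streams for the equivalence bound; full-trajectory cohorts of 2–8
participants per group (a trajectory-level cohort of 8/group is ~11,000
trials); 50 aim-level cohorts of 30 participants for parameter recovery;
50 observers × 480 trials for staircase calibration; 1,000 simulated null
cohorts for type-I calibration (null cohorts have zero learning gain, so
per-trial angles are pure motor noise, and all period windows match the
real analysis). The "mean zero" checks on after-effect, transfer and
corrected generalization use a 2-standard-error band around zero, the
tightest criterion a stochastic estimate can meet reliably.

## Known limitations

* The camera model is the equivalence-exact per-axis pinhole form; a
  renderer-faithful gnomonic camera would differ at second order in angle.
* The learner is a convenience for validating the measurement chain;
  fitting it to real data estimates (A, B) under its own assumptions only.
* `reproduce` expects deposited tables laid out locally with a column
  mapping supplied by the user; no network access is attempted.
* Bayes factors are BIC approximations (see above).
* Trials with non-monotone timestamps or long gaps are excluded, not
  repaired.
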