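# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the package's tests establish.

## Session design

A session is 240 reaching trials to a single target at 0° with error-clamped
cursor feedback whose direction follows
`clamp(t) = sign · A · sin(2π(t−1)/P)` for 1-based trial `t`, amplitude
`A = 10°` and cycle length `P = 20` trials (12 cycles per session); trial 1
is exactly 0°. The sequence is built by tiling one exactly computed cycle, so
periodicity is bit-exact and the DFT carries all energy in the 12
cycles/session bin. Angles are degrees throughout, positive counter-clockwise
from the target; whether the first excursion is clockwise or
counter-clockwise is not determined by the design itself, so the generator
exposes `clamp_sign` (default +1) rather than guessing.

The two task variants differ only in the wager: *sensorimotor* (arc centered
on the target, initial subtense uniform on [1°, 40°], points 10 → 0 between
2° and 40°) and *motor-awareness* (arc centered on the reported direction,
[1°, 20°], points 10 → 0 between 2° and 20°).

## Adaptation model

The data-generating process for implicit adaptation is a first-order linear
state-space learner,

    x(1) = 0,   x(t+1) = a·x(t) − b·clamp(t),   reach(t) = x(t) + ε_m(t),

with retention `a ∈ [0, 1)`, learning rate `b ∈ [0, 1)` and i.i.d. motor
noise ε_m ~ N(0, σ_m²). Because the clamp "error" is independent of the
reach, the learner is driven by the clamp alone and the model is fully
linear; its sinusoidal steady state has the closed form of the transfer
function H(z) = −b/(z − a) at z = e^{iω}, ω = 2π/P:

    gain = b / |e^{iω} − a|,
    lag  = (−arg H / ω) mod P  ∈  (P/2, P)   for every a ∈ [0, 1).

The lag is always more than half a cycle: the sign inversion contributes
exactly P/2 (= 10 trials) and the learner's memory adds a strictly positive
delay. `lti_response` implements this closed form and is the exact oracle for
the simulator (they agree to ~1e−13 when σ_m = 0).

**Default calibration.** The lag of a first-order learner depends on the
retention alone, and the gain scales linearly with the learning rate. The
defaults `a = 0.5`, `b = 0.5468` are chosen so the steady-state reach lags
the clamp by 11.91 trials with amplitude 10.0° — the group-level adaptation
behavior this design elicits (reach lags of ~11.9 trials and amplitudes near
the clamp amplitude). These are documented generator defaults, not fits to
any dataset.

## Proprioception, reports and the awareness model

The sensed hand direction is `s ~ N(e, σ_p²)`, independent across trials. An
ideal observer who knows both noise levels reports the MAP estimate of its
own reach under the prior e ~ N(0, σ_m²) (the aim is the target):

    i = k·s,   k = r_p/(r_p + r_m) = σ_m²/(σ_m² + σ_p²),

i.e. the sensed direction shrunk toward the aim. From the experimenter's
side, a pre-test trial d = (e, i) has likelihood

    p(d | σ_m, σ_p) = φ(e; 0, σ_m²) · φ(i; k·e, k²σ_p²),

with no additional dial noise, and (σ_m, σ_p) are fitted per participant by
maximizing the summed log likelihood.

**Fitter.** The objective is parameterized in log σ and maximized by
Nelder–Mead seeded from the best node of an 11×11 log-spaced grid over
σ ∈ [0.5°, 30°], with a hard box of [0.1°, 50°] enforced through the
optimizer's bounds. Defaults for grid, box and convergence tolerances are
package choices; nothing in the model prescribes them. Two degeneracies are
handled explicitly: fewer than 2 trials or all-identical endpoints raise
`FitError` (σ_m is unidentifiable), and data from the noiseless-report limit
(σ_p → 0 implies k → 1, so reports coincide with endpoints) pin σ_p̂ at the
lower bound rather than diverging. Note the limit must be taken
self-consistently: reports lying exactly on `k₀·e` for an *interior*
generating k₀ do **not** drive σ_p̂ to zero, because lowering σ_p̂ also moves
the model's slope k̂ toward 1 and away from the data's slope — the MLE is
then interior.

Pooling: the fitter accepts any pooled list of (e, i) pairs (the pre-test
pools 40 + 40 trials across two sessions into one 80-trial fit) and records
`n_trials`.

## Report and confidence policies

Report policies (motor-awareness task only) generate the hypothesized
response patterns: `motor_plan` (report the aim, 0°), `feedback_pulled`
(report the clamp direction), `proprioceptive_antiphase` (the MAP-shrunk
sensed direction `k·s` — the ideal observer), and `weighted_combination`
(`w·clamp + (1−w)·k·s`). All add N(0, report_noise_sd²); the ideal-observer
model assumes zero dial noise, so fitting data from a noisy or non-ideal
policy probes robustness, not correctness.

Confidence policies map trial signals to an arc subtense:
`prior_only` (constant c0), `feedback_driven` (c0 + c1·|clamp|),
`hand_driven` (c0 + c1·|sensed − target|), `mismatch_driven`
(c0 + c1·|clamp − sensed|), each plus Gaussian noise and clipped to
[0.1°, task max arc]. The rectifications make sign-invariant policies
oscillate at twice the clamp frequency (24 cycles/session) following a
negative cosine (widest arcs — lowest confidence — at peak clamp distance).
Policy defaults (c0 = 6°, c1 = 0.5 deg/deg, noise SD 2°, w = 0.5) are chosen
to give arc ranges and capture rates in the plausible regime for these tasks
(mean arcs around 8–12°, capture rates of a few tens of percent); σ_m = 4°
and σ_p = 7° sit at the group-mean noise levels measured with this paradigm.

Cohorts draw per-participant RNG streams from a spawned `SeedSequence`, so
each participant's data are independent of cohort size and generation order,
and the true generating parameters are returned alongside for recovery
studies. Aborted/repeated trials are not simulated: analyzed tables are
complete by construction.

## Spectral analysis and lag conventions

`fourier_component` projects the mean-removed series onto
`exp(−iω(t−1))`, ω = 2πf/N, and reports `2|c|/N` so a pure sinusoid of
amplitude A returns A. Only integer (design-commensurate) frequencies are
accepted. Series are demeaned before projection — confidence arcs are
strictly positive, and the DC term is removed deliberately; no detrending is
applied.

Phase becomes a trial lag against one of two references:

- `clamp_sine` (reach and report, at 12 cycles/session): lag wrapped to
  [0, 20); exact anti-phase = 10 trials, an adapting learner lands in
  (10, 20).
- `negative_cosine` (confidence, at 24 cycles/session): lag wrapped to
  [−5, 5); 0 = arcs widest exactly at peak clamp distance, negative lags mean
  the arc peak precedes it, |5| = anti-phase.

Values within 1e−9 trials of the open upper edge are snapped to the closed
lower edge, so a component at exact anti-phase (or exact zero lag) is
reported at the canonical edge value rather than at `edge − ε` from float
round-off.

**Permutation test.** Trial order is shuffled uniformly (default 100,000
shuffles; analyses in tests use 10³–2×10³), the amplitude at the target
frequency recomputed each time, and the add-one estimator
`p = (1 + #{null ≥ observed}) / (1 + n_shuffles)` reported, so p is never 0
and the test is exactly valid under exchangeability. Significance is
`p < 0.01`, operationalizing the "larger than 99% of shuffles" criterion;
the add-one estimator makes the strict/non-strict boundary distinction moot.
A constant series yields amplitude 0 and p = 1 (not an error). Shuffling is
chunked (20,000 rows at a time) to bound memory at the default shuffle count.

## Wager scoring

An arc of subtense `w` centered at `c` captures the reach `e` iff
`|e − c| ≤ w/2` — the full subtense extends equidistantly both ways and the
boundary is inclusive (the geometry does not determine open vs closed; the
inclusive convention is declared once here). Captured trials earn
`max_points · clip((zero_arc − w)/(zero_arc − full_arc), 0, 1)`; misses earn
0. Points are real-valued; no integer rounding is applied. Directions are
validated to lie within ±180° of the target and no angular wrap-around is
handled — reach directions in this paradigm live within a few tens of
degrees of the target.

## Pipeline statistics

- *Engagement check*: the starting arc is random, so an engaged participant's
  final arcs should be uncorrelated with it; a session is flagged when the
  Pearson correlation is significant at 0.05 or the final arcs never changed
  (constant, or identical to the initial ones). Flags are logged and carried
  in the summary, never silently dropped.
- *Mismatch correlation*: Pearson r between the confidence arc and
  |clamp − reach| (two-sided p). *Report-error correlation*: the same against
  |report − reach| — the distance the wager actually pays on. Zero-variance
  inputs return r = 0 with an explicit `degenerate` flag instead of NaN;
  two-sided p-values throughout.
- *Group comparison*: pooled-variance Student t with df = n_a + n_b − 2
  (11 vs 9 participants gives df = 18), not Welch.
- `reproduce()` chains simulate → fit → analyze → summarize for a cohort
  (default 20 participants × 2 tasks, plus an 80-trial pre-test each) and is
  byte-identical under a fixed seed and config.

## What the synthetic data do and do not establish

The generator reproduces the statistical structure the analyses assume:
sinusoidal forcing, linear adaptation with anti-phase lag > 10 trials,
Gaussian motor/proprioceptive noise, MAP-shrunk reports, policy-driven
confidence, and the wager bookkeeping. It does not emulate within-reach
kinematics, proprioceptive recalibration drift, trial aborts, saturating or
nonlinear adaptation, learning of the wager itself over a session, or
individual strategy switches mid-session. Passing tests therefore establish
correctness of the estimators and conventions on data satisfying the model's
assumptions — not that real participants satisfy them. Reproducing any real
cohort's participant-level numbers requires that cohort's data and is out of
scope here.

## Problem sizes used in the checks

Parameter-recovery checks fit 200 simulated participants × 80 pre-test
trials at the group-mean truth (σ_m = 3.99°, σ_p = 7.16°) and require mean
estimates within 10%. Type-I calibration of the permutation test runs 1,000
i.i.d.-noise sessions at 2,000 shuffles each against the 1% criterion.
Simulator-vs-oracle checks run the learner 100 cycles past its transient so
the remaining transient is below float precision. Unit tests use 200–2,000
shuffles; the 100,000-shuffle default matches the analysis convention and is
overridable everywhere.
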