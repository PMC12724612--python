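# clampconf

Simulation and analysis of **implicit visuomotor adaptation under a
sinusoidal error clamp**, and of its effect on **motor awareness** and
**confidence wagering**.

## The scientific problem

In an error-clamp reaching experiment the cursor's radial progress follows
the hand but its *direction* is fixed by the experimenter, so the visual
"error" is independent of what the hand actually does. Participants are told
to ignore the cursor and reach straight at a target (0°), yet their reaches
drift *opposite* to the clamped feedback — implicit adaptation. Here the
clamp direction varies sinusoidally across trials (±10°, one cycle every 20
trials, 12 cycles per 240-trial session, starting at exactly 0°), which turns
the paradigm into a system-identification problem: the adaptation, the
reported hand position, and the trial-by-trial confidence wager can each be
probed for a spectral component at (or at twice) the driving frequency.

The package provides:

- **Session design** — the clamp schedule and task parameters
  (`SessionDesign`, `make_clamp_sequence`).
- **Generative observer** — a first-order state-space learner
  `x(t+1) = a·x(t) − b·clamp(t)` with motor noise σ_m and proprioceptive
  noise σ_p, plus report and confidence *policies* (prior-only,
  feedback-driven, hand-driven, mismatch-driven) that generate full synthetic
  sessions and cohorts (`ObserverParams`, `simulate_session`,
  `simulate_cohort`). The learner's steady-state gain and trial lag have a
  closed form (`lti_response`) used as an analytic oracle.
- **Motor-awareness model** — the Bayesian ideal observer that reports the
  MAP estimate of its own reach direction,
  `i = [r_p/(r_p+r_m)]·s` with reliabilities `r = 1/σ²`, and the
  maximum-likelihood fitter for (σ_m, σ_p) from (endpoint, report) pairs,
  using the per-trial likelihood
  `p(e, i | σ_m, σ_p) = φ(e; 0, σ_m²) · φ(i; k·e, k²σ_p²)`,
  `k = σ_m²/(σ_m²+σ_p²)` (`fit_awareness`).
- **Spectral analysis** — single-frequency Fourier components, conversion of
  phase to *trial lag* against the clamp-sine reference (reach/report, 12
  cycles/session; anti-phase = 10-trial lag) or the negative-cosine reference
  (confidence, 24 cycles/session; anti-phase = 5-trial lag), and a
  trial-shuffle permutation test with the add-one p-value estimator
  (`fourier_component`, `phase_to_lag`, `permutation_test`,
  `analyze_signals`).
- **Wager scoring** — points decrease linearly from 10 for confidence arcs
  ≤ 2° to 0 at ≥ 40° (sensorimotor) or ≥ 20° (motor-awareness) and are paid
  only when the arc encloses the true reach (`WagerRule`, `score_trial`).
- **Pipeline** — session CSV I/O, engagement checks, mismatch–confidence
  correlations, pooled-variance group comparison, and an end-to-end
  `reproduce()` that simulates a cohort, fits, analyzes and summarizes.

## Worked example

```python
import numpy as np
from clampconf import (SessionDesign, ObserverParams, simulate_session,
                       analyze_signals, lti_response, simulate_pretest,
                       fit_awareness)

design = SessionDesign()                       # 240 trials, ±10°, 12 cycles
params = ObserverParams(seed=7)                # adapting, mismatch-driven agent
session = simulate_session(params, design)

spectra = analyze_signals(session, design, n_shuffles=2000, rng=0)
print(f"reach: amp {spectra.reach.amplitude:.2f} deg, "
      f"lag {spectra.reach.trial_lag:.2f} trials, p={spectra.reach.p_value:.4g}")
print(f"conf : amp {spectra.confidence.amplitude:.2f} deg, "
      f"lag {spectra.confidence.trial_lag:.2f} trials, "
      f"significant={spectra.confidence.significant}")
print("oracle gain/lag:", lti_response(params.retention, params.learning_rate, 20))

pre = simulate_pretest(3.99, 7.16, 80, np.random.default_rng(1))
fit = fit_awareness(pre["reach_dir"].to_numpy(), pre["report_dir"].to_numpy())
print(f"fitted sigma_m {fit.sigma_m_hat:.2f}, sigma_p {fit.sigma_p_hat:.2f}")
```

prints

```
reach: amp 10.04 deg, lag 11.77 trials, p=0.0004998
conf : amp 3.26 deg, lag 0.97 trials, significant=True
oracle gain/lag: (1.000078199508626, 11.91193806470505)
fitted sigma_m 3.52, sigma_p 5.94
```

The reach carries a strong 12-cycle component lagging the clamp by ~11.9
trials — anti-phase (10 trials) plus a learning delay — matching the
transfer-function oracle; the mismatch-driven confidence arcs oscillate at
the doubled frequency (24 cycles/session) near zero lag; and the pre-test
fit recovers the generating noise SDs to within sampling error of an
80-trial session.

A command-line interface mirrors the pipeline:

```bash
clampconf simulate --seed 1 --out cohort/
clampconf analyze --input cohort/participant01_sensorimotor.csv \
    --task sensorimotor --shuffles 2000 --seed 1
clampconf fit-awareness --input pretest.csv
clampconf reproduce --seed 1 --out results/
```

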