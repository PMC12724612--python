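"""Generative observer: simulates full error-clamp sessions.

Implicit adaptation is modeled as a first-order linear state-space learner.
With retention ``a`` and learning rate ``b`` the latent adapted state x obeys

    x(1) = 0,    x(t+1) = a * x(t) - b * clamp(t)

and the executed reach is ``reach(t) = target + x(t) + motor noise``.  Driven
by a sinusoidal clamp the learner settles into a sinusoid of the same
frequency whose gain and trial lag have the closed form of the transfer
function H(z) = -b / (z - a) evaluated at z = exp(i*2*pi/P); that closed form
(`lti_response`) is the analytic oracle for the simulator.  Because the error
signal of an error clamp is independent of the reach, the learner is driven by
the clamp alone, and the steady-state reach is anti-phase to the clamp plus a
learning delay: the lag always exceeds half a cycle (10 trials at defaults).

Proprioception senses the executed reach with Gaussian noise (s ~ N(e,
sigma_p^2)).  Report policies (motor-awareness task) and confidence policies
(both tasks) implement the qualitative response patterns an observer could
show: ignoring everything, tracking the (false) feedback, tracking the sensed
hand, or mixing the cues.

Default generative parameters are calibrated to the group-level behavior the
design is meant to elicit: retention 0.5 and learning rate 0.5468 give a
steady-state reach lag of 11.91 trials and amplitude 10.0 deg at the default
20-trial cycle; sigma_m = 4 deg and sigma_p = 7 deg sit at the group-mean
noise levels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .awareness import map_report, shrinkage_weight
from .design import ConfigurationError, SessionDesign, Task, make_clamp_sequence
from .wager import WagerRule, capture, score_trial

__all__ = [
    "ObserverParams",
    "REPORT_POLICIES",
    "CONFIDENCE_POLICIES",
    "lti_response",
    "simulate_adaptation",
    "sense_hand",
    "generate_report",
    "generate_confidence",
    "simulate_session",
    "simulate_pretest",
    "simulate_cohort",
]

REPORT_POLICIES = ("motor_plan", "feedback_pulled", "proprioceptive_antiphase", "weighted_combination")
CONFIDENCE_POLICIES = ("prior_only", "feedback_driven", "hand_driven", "mismatch_driven")

#: Smallest confidence arc the simulator will emit (deg); keeps arcs positive.
ARC_FLOOR = 0.1


@dataclass(frozen=True)
class ObserverParams:
    """Generative agent parameters.

    sigma_m, sigma_p
        Motor and proprioceptive noise SDs (deg), both > 0.
    retention, learning_rate
        State-space learner coefficients, each in [0, 1).
    report_policy
        One of ``REPORT_POLICIES`` for motor-awareness sessions; must be None
        for sensorimotor sessions (no direction report is collected there).
    report_weight
        Mixing weight w on the clamp-pulled component of the
        ``weighted_combination`` report policy, in [0, 1].
    report_noise_sd
        Additive Gaussian noise on the report (deg).  The ideal observer of
        the awareness model has none; nonzero values make non-ideal agents.
    confidence_policy
        One of ``CONFIDENCE_POLICIES``.
    conf_baseline, conf_gain
        Arc policy intercept c0 (deg) and slope c1 (deg per deg of signal).
    conf_noise_sd
        Additive Gaussian noise on the arc subtense (deg).
    seed
        RNG seed for `simulate_session`; None draws fresh entropy.
    """

    sigma_m: float = 4.0
    sigma_p: float = 7.0
    retention: float = 0.5
    learning_rate: float = 0.5468
    report_policy: str | None = None
    report_weight: float = 0.5
    report_noise_sd: float = 2.0
    confidence_policy: str = "mismatch_driven"
    conf_baseline: float = 6.0
    conf_gain: float = 0.5
    conf_noise_sd: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_m <= 0 or self.sigma_p <= 0:
            raise ConfigurationError("sigma_m and sigma_p must be positive")
        if not (0.0 <= self.retention < 1.0):
            raise ConfigurationError("retention must lie in [0, 1)")
        if not (0.0 <= self.learning_rate < 1.0):
            raise ConfigurationError("learning_rate must lie in [0, 1)")
        if self.report_policy is not None and self.report_policy not in REPORT_POLICIES:
            raise ConfigurationError(f"unknown report_policy {self.report_policy!r}")
        if self.confidence_policy not in CONFIDENCE_POLICIES:
            raise ConfigurationError(f"unknown confidence_policy {self.confidence_policy!r}")
        if not (0.0 <= self.report_weight <= 1.0):
            raise ConfigurationError("report_weight must lie in [0, 1]")
        if self.conf_baseline < 0 or self.conf_gain < 0:
            raise ConfigurationError("conf_baseline and conf_gain must be >= 0")


def lti_response(retention: float, learning_rate: float, trials_per_cycle: int) -> tuple[float, float]:
    """Steady-state (gain, trial lag) of the learner driven at the design frequency.

    ``gain`` is the ratio of reach-sinusoid amplitude to clamp amplitude;
    ``lag`` is in trials, wrapped to [0, trials_per_cycle), and exceeds half a
    cycle for every retention in [0, 1) — anti-phase plus a learning delay.
    """
    if retention >= 1.0:
        raise ValueError("retention >= 1 gives an unstable (non-decaying) learner")
    if retention < 0:
        raise ValueError("retention must be >= 0")
    omega = 2.0 * np.pi / trials_per_cycle
    g = -learning_rate / (np.exp(1j * omega) - retention)
    gain = float(np.abs(g))
    lag = float((-np.angle(g) / omega) % trials_per_cycle)
    return gain, lag


def simulate_adaptation(
    params: ObserverParams, clamp: Sequence[float], rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(latent adapted state, executed reach) over a clamp sequence.

    The recursion x(t+1) = a*x(t) - b*clamp(t) with x(1) = 0 is run by a
    digital filter; reaches add i.i.d. motor noise around target + x.
    """
    clamp = np.asarray(clamp, dtype=float)
    if not np.all(np.isfinite(clamp)):
        raise ValueError("clamp sequence must be finite")
    rng = np.random.default_rng() if rng is None else rng
    # H(z) = -b z^{-1} / (1 - a z^{-1}): one-trial delay, leaky accumulation.
    x = lfilter([0.0, -params.learning_rate], [1.0, -params.retention], clamp)
    reach = x + rng.normal(0.0, params.sigma_m, size=clamp.size)
    return x, reach


def sense_hand(reach_dir, sigma_p: float, rng: np.random.Generator):
    """Proprioceptively sensed direction: s ~ N(reach, sigma_p^2), i.i.d. across trials."""
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    reach_dir = np.asarray(reach_dir, dtype=float)
    return reach_dir + rng.normal(0.0, sigma_p, size=reach_dir.shape)


def generate_report(
    sensed_dir, clamp_dir, params: ObserverParams, rng: np.random.Generator | None = None
):
    """Reported hand direction under the agent's report policy (motor-awareness task).

    motor_plan
        Report the aim: 0 deg regardless of the trial.
    feedback_pulled
        Report where the (false) cursor went.
    proprioceptive_antiphase
        MAP-shrunk sensed direction k*s — the awareness model's ideal report,
        which tracks the anti-phase adapted hand at reduced amplitude.
    weighted_combination
        w * clamp + (1 - w) * k*s.

    All policies add N(0, report_noise_sd^2) noise when an rng is given.
    """
    if params.report_policy is None:
        raise ConfigurationError("generate_report needs a report_policy (motor-awareness task)")
    sensed = np.asarray(sensed_dir, dtype=float)
    clamp = np.asarray(clamp_dir, dtype=float)
    shrunk = map_report(sensed, params.sigma_m, params.sigma_p)
    if params.report_policy == "motor_plan":
        report = np.zeros(np.broadcast(sensed, clamp).shape)
    elif params.report_policy == "feedback_pulled":
        report = clamp.astype(float).copy()
    elif params.report_policy == "proprioceptive_antiphase":
        report = shrunk
    else:  # weighted_combination
        w = params.report_weight
        report = w * clamp + (1.0 - w) * shrunk
    if rng is not None and params.report_noise_sd > 0:
        report = report + rng.normal(0.0, params.report_noise_sd, size=report.shape)
    return report


def generate_confidence(
    clamp_dir,
    sensed_dir,
    params: ObserverParams,
    design: SessionDesign,
    rng: np.random.Generator | None = None,
):
    """Confidence-arc subtense (deg) under the agent's confidence policy.

    prior_only
        Constant c0: confidence from prospective knowledge alone.
    feedback_driven
        c0 + c1*|clamp|: arcs widen with the cursor's distance from the
        target — a rectified response, so it oscillates at twice the clamp
        frequency (24 cycles per session at defaults).
    hand_driven
        c0 + c1*|sensed - target|.
    mismatch_driven
        c0 + c1*|clamp - sensed|: arcs widen with the visuo-proprioceptive
        conflict.

    Noise is added, then arcs are clipped to [ARC_FLOOR, task's maximum arc].
    """
    clamp = np.asarray(clamp_dir, dtype=float)
    sensed = np.asarray(sensed_dir, dtype=float)
    target = design.target_direction
    if params.confidence_policy == "prior_only":
        arc = np.full(np.broadcast(clamp, sensed).shape, params.conf_baseline, dtype=float)
    elif params.confidence_policy == "feedback_driven":
        arc = params.conf_baseline + params.conf_gain * np.abs(clamp - target)
    elif params.confidence_policy == "hand_driven":
        arc = params.conf_baseline + params.conf_gain * np.abs(sensed - target)
    else:  # mismatch_driven
        arc = params.conf_baseline + params.conf_gain * np.abs(clamp - sensed)
    if rng is not None and params.conf_noise_sd > 0:
        arc = arc + rng.normal(0.0, params.conf_noise_sd, size=arc.shape)
    return np.clip(arc, ARC_FLOOR, design.wager_max_arc)


def simulate_session(
    params: ObserverParams, design: SessionDesign, seed: int | None = None
) -> pd.DataFrame:
    """One complete session table, fully reproducible from the seed.

    Columns: trial (1-based), clamp_dir, adapt_state (latent), reach_dir,
    sensed_dir (latent), report_dir (motor-awareness only), initial_arc,
    confidence_arc, captured, points.  The wager is scored against the task's
    rule: arc centered on the target (sensorimotor) or on the report
    (motor-awareness).
    """
    if design.task is Task.SENSORIMOTOR and params.report_policy is not None:
        raise ConfigurationError(
            "report_policy given for a sensorimotor session (no direction report is collected)"
        )
    if design.task is Task.MOTOR_AWARENESS and params.report_policy is None:
        raise ConfigurationError("a motor-awareness session needs a report_policy")

    rng = np.random.default_rng(params.seed if seed is None else seed)
    clamp = make_clamp_sequence(design)
    adapt, reach = simulate_adaptation(params, clamp, rng)
    sensed = sense_hand(reach, params.sigma_p, rng)

    data: dict[str, np.ndarray] = {
        "trial": np.arange(1, design.n_trials + 1),
        "clamp_dir": clamp,
        "adapt_state": adapt,
        "reach_dir": reach,
        "sensed_dir": sensed,
    }
    rule = WagerRule.for_design(design)
    if design.task is Task.MOTOR_AWARENESS:
        report = np.asarray(generate_report(sensed, clamp, params, rng))
        data["report_dir"] = report
        center = report
    else:
        center = np.full(design.n_trials, design.target_direction)

    lo, hi = design.initial_arc_range
    data["initial_arc"] = rng.uniform(lo, hi, size=design.n_trials)
    arc = np.asarray(generate_confidence(clamp, sensed, params, design, rng))
    data["confidence_arc"] = arc
    data["captured"] = capture(center, arc, reach)
    data["points"] = score_trial(rule, center, arc, reach)
    return pd.DataFrame(data)


def simulate_pretest(
    sigma_m: float, sigma_p: float, n_trials: int = 80, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Motor-awareness pre-test: no-feedback reaches with MAP-ideal reports.

    e ~ N(0, sigma_m^2), s ~ N(e, sigma_p^2), i = k*s — exactly the forward
    process the awareness fitter assumes (no dial noise).
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    e = rng.normal(0.0, sigma_m, size=n_trials)
    s = sense_hand(e, sigma_p, rng)
    i = map_report(s, sigma_m, sigma_p)
    return pd.DataFrame({"trial": np.arange(1, n_trials + 1), "reach_dir": e, "report_dir": i})


def simulate_cohort(
    n_participants: int,
    param_sampler: Callable[[np.random.Generator], ObserverParams] | ObserverParams,
    design: SessionDesign,
    seed: int | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Independent sessions for a cohort, plus the table of true parameters.

    Per-participant RNG streams are spawned from the master seed, so each
    participant's data are independent of cohort size and generation order.
    ``param_sampler`` may be a callable drawing ObserverParams from an rng, or
    a single ObserverParams used for everyone (noise still differs).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_participants)
    sessions: list[pd.DataFrame] = []
    rows = []
    for pid, child in enumerate(children, start=1):
        param_rng = np.random.default_rng(child)
        if callable(param_sampler):
            params = param_sampler(param_rng)
        else:
            params = param_sampler
        session_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        params = replace(params, seed=session_seed)
        sessions.append(simulate_session(params, design))
        row = {"participant": pid, "task": design.task.value, "seed": session_seed}
        row.update({k: v for k, v in params.__dict__.items() if k != "seed"})
        rows.append(row)
    return sessions, pd.DataFrame(rows)
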