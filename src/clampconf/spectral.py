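"""Fourier component extraction, trial-lag conventions, and permutation testing.

A session-long trial series is probed at a single design-commensurate
frequency f (cycles per session): the mean-removed series is projected onto
exp(-i*omega*(t-1)), omega = 2*pi*f/N, and amplitude = 2|c|/N so a pure
sinusoid of amplitude A returns A.

Phase is converted to a *trial lag* against one of two reference waveforms:

clamp_sine
    The clamp itself, A*sin(omega*(t-1)) — used for reach and report series
    at the clamp frequency (12 cycles/session at defaults).  Lag is wrapped
    to [0, period): a series in exact anti-phase to the clamp lags by half a
    cycle (10 trials at defaults), and an adapting learner lags a few trials
    more.
negative_cosine
    -cos at the doubled frequency (24 cycles/session at defaults) — used for
    confidence arcs, which are widest (lowest confidence) when the clamp is
    farthest from the target and so follow a negative cosine with maximum
    confidence at clamp-zero phase.  Lag is wrapped to [-period/2, period/2):
    negative lags mean the arc peak precedes the peak clamp distance, and
    |lag| = half a cycle (5 trials) is anti-phase.

Significance of a component is assessed by a trial-order permutation test:
shuffling destroys serial structure while preserving the value multiset, the
amplitude is recomputed per shuffle, and p uses the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_shuffles), so p is never exactly 0.
A component is significant when p < 0.01 (the "larger than 99% of shuffles"
criterion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import SessionDesign, Task

__all__ = [
    "SpectralComponent",
    "PermutationResult",
    "SessionSpectra",
    "fourier_component",
    "phase_to_lag",
    "permutation_test",
    "analyze_signals",
]

#: Significance criterion on the permutation p-value.
ALPHA = 0.01

#: Shuffles used by default; tests and quick looks pass far fewer.
DEFAULT_N_SHUFFLES = 100_000

_REFERENCES = ("clamp_sine", "negative_cosine")


@dataclass(frozen=True)
class SpectralComponent:
    """One probed frequency of one trial series."""

    frequency: int            # cycles per session
    amplitude: float          # same units as the series (deg / arc-deg)
    phase: float              # radians, argument of the complex projection
    trial_lag: float          # trials, wrapped per the reference convention
    p_value: float            # add-one permutation p; 1.0 if untested
    significant: bool
    reference: str            # "clamp_sine" | "negative_cosine"


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    significant: bool
    observed_amplitude: float
    null_mean: float
    null_sd: float
    null_q99: float
    n_shuffles: int


@dataclass(frozen=True)
class SessionSpectra:
    """Per-signal components for one session, at the design's frequency pairing."""

    reach: SpectralComponent
    confidence: SpectralComponent
    confidence_mean: float            # mean arc, the plotted line when non-significant
    report: Optional[SpectralComponent] = None


def _check_frequency(n: int, frequency) -> int:
    f = float(frequency)
    if f != int(f):
        raise ValueError(
            f"frequency must be an integer number of cycles per session (got {frequency}); "
            "only design-commensurate frequencies are meaningful"
        )
    f = int(f)
    if not (0 < f < n / 2):
        raise ValueError(f"frequency must lie in (0, n_trials/2) = (0, {n / 2:g}), got {f}")
    return f


def _kernel(n: int, f: int) -> np.ndarray:
    return np.exp(-2j * np.pi * f * np.arange(n) / n)


def fourier_component(series, frequency) -> tuple[float, float]:
    """(amplitude, phase) of the mean-removed series at ``frequency`` cycles/session.

    Amplitude is normalized as 2|c|/N so a unit sinusoid yields 1; phase is
    the argument of the complex projection c = sum_t x(t) exp(-i*omega*(t-1)).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    f = _check_frequency(n, frequency)
    c = (x - x.mean()) @ _kernel(n, f)
    return float(2.0 * np.abs(c) / n), float(np.angle(c))


def phase_to_lag(phase: float, frequency, reference: str, design: SessionDesign) -> float:
    """Trial lag of a component relative to the reference waveform.

    clamp_sine expects the clamp frequency (cycles_per_session) and wraps to
    [0, period); negative_cosine expects the doubled frequency and wraps to
    [-period/2, period/2).  ``period = n_trials / frequency`` trials.
    """
    if reference not in _REFERENCES:
        raise ValueError(f"unknown reference {reference!r}")
    f = _check_frequency(design.n_trials, frequency)
    if reference == "clamp_sine" and f != design.cycles_per_session:
        raise ValueError(
            f"clamp_sine reference applies at the clamp frequency "
            f"({design.cycles_per_session} cycles/session), got {f}"
        )
    if reference == "negative_cosine" and f != 2 * design.cycles_per_session:
        raise ValueError(
            f"negative_cosine reference applies at the doubled frequency "
            f"({2 * design.cycles_per_session} cycles/session), got {f}"
        )
    period = design.n_trials / f
    omega = 2.0 * np.pi / period
    # values within float error of the open upper edge snap to the closed lower edge
    edge_tol = 1e-9
    if reference == "clamp_sine":
        # pure sin(omega*(t-1)) projects to phase -pi/2
        lag = (-(phase + np.pi / 2.0) / omega) % period
        if period - lag < edge_tol:
            lag = 0.0
    else:
        # pure -cos(omega*(t-1)) projects to phase pi
        lag = (np.pi - phase) / omega
        lag = (lag + period / 2.0) % period - period / 2.0
        if period / 2.0 - lag < edge_tol:
            lag = -period / 2.0
    return float(lag)


def permutation_test(
    series,
    frequency,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | int | None = None,
    alpha: float = ALPHA,
    _chunk: int = 20_000,
) -> PermutationResult:
    """Trial-order permutation test of the amplitude at ``frequency``.

    The series is shuffled uniformly ``n_shuffles`` times, the component
    amplitude recomputed each time, and the add-one p-value reported:
    p = (1 + #{null >= observed}) / (1 + n_shuffles).  A constant series has
    amplitude 0 and p = 1 (never significant) — not an error.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    x = np.asarray(series, dtype=float)
    n = x.size
    f = _check_frequency(n, frequency)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    observed, _ = fourier_component(x, f)
    xc = x - x.mean()  # the mean is shuffle-invariant; demean once
    kernel = _kernel(n, f)
    null = np.empty(n_shuffles)
    done = 0
    while done < n_shuffles:
        m = min(_chunk, n_shuffles - done)
        perms = rng.permuted(np.tile(xc, (m, 1)), axis=1)
        null[done : done + m] = 2.0 * np.abs(perms @ kernel) / n
        done += m
    exceed = int(np.count_nonzero(null >= observed))
    p = (1.0 + exceed) / (1.0 + n_shuffles)
    return PermutationResult(
        p_value=float(p),
        significant=bool(p < alpha),
        observed_amplitude=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        null_q99=float(np.quantile(null, 0.99)),
        n_shuffles=int(n_shuffles),
    )


def _component(
    series, f: int, reference: str, design: SessionDesign, n_shuffles, rng, alpha
) -> SpectralComponent:
    amplitude, phase = fourier_component(series, f)
    perm = permutation_test(series, f, n_shuffles=n_shuffles, rng=rng, alpha=alpha)
    return SpectralComponent(
        frequency=f,
        amplitude=amplitude,
        phase=phase,
        trial_lag=phase_to_lag(phase, f, reference, design),
        p_value=perm.p_value,
        significant=perm.significant,
        reference=reference,
    )


def analyze_signals(
    session: pd.DataFrame,
    design: SessionDesign,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    rng: np.random.Generator | int | None = None,
    alpha: float = ALPHA,
) -> SessionSpectra:
    """Spectral components for every signal a session provides.

    Reach (and, in the motor-awareness task, the direction report) are probed
    at the clamp frequency with the clamp_sine reference; confidence arcs at
    the doubled frequency with the negative_cosine reference.  The mean arc is
    reported alongside — it is the meaningful summary when the confidence
    component is not significant.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    f0 = design.cycles_per_session
    missing = {"reach_dir", "confidence_arc"} - set(session.columns)
    if missing:
        raise ValueError(f"session table lacks required columns: {sorted(missing)}")
    reach = _component(session["reach_dir"].to_numpy(), f0, "clamp_sine", design, n_shuffles, rng, alpha)
    report = None
    if design.task is Task.MOTOR_AWARENESS:
        if "report_dir" not in session.columns:
            raise ValueError("motor-awareness session lacks the report_dir column")
        report = _component(
            session["report_dir"].to_numpy(), f0, "clamp_sine", design, n_shuffles, rng, alpha
        )
    conf = _component(
        session["confidence_arc"].to_numpy(), 2 * f0, "negative_cosine", design, n_shuffles, rng, alpha
    )
    return SessionSpectra(
        reach=reach,
        confidence=conf,
        confidence_mean=float(session["confidence_arc"].mean()),
        report=report,
    )
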