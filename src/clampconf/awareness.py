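"""Bayesian ideal-observer model of motor awareness and its ML fitter.

The participant aims at a target straight ahead (0 deg).  The executed reach
direction ``e`` scatters around the aim with motor noise, e ~ N(0, sigma_m^2),
and proprioception returns a noisy sense of it, s ~ N(e, sigma_p^2).  Knowing
both noise levels, an ideal observer reports the MAP estimate of the reach
direction, which shrinks the sensed direction toward the aim:

    i = k * s,    k = r_p / (r_p + r_m) = sigma_m^2 / (sigma_m^2 + sigma_p^2)

with reliabilities r_m = 1/sigma_m^2, r_p = 1/sigma_p^2.  From the
experimenter's side a trial d = (e, i) therefore has likelihood

    p(d | sigma_m, sigma_p) = N(e; 0, sigma_m^2) * N(i; k*e, k^2 * sigma_p^2)

(the report itself is assumed free of dial noise), and (sigma_m, sigma_p) are
estimated per participant by maximizing the summed log likelihood over an
80-trial pre-test (trials are independent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "AwarenessTrial",
    "AwarenessFit",
    "FitError",
    "shrinkage_weight",
    "map_report",
    "trial_loglik",
    "total_loglik",
    "fit_awareness",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

# ML search box (deg): coarse grid per the fitter design, hard bounds for the
# local refinement.  Degenerate data (reports exactly on the shrunk mean) pin
# sigma_p at the lower bound rather than diverging.
GRID_RANGE = (0.5, 30.0)
GRID_SIZE = 11
SIGMA_BOUNDS = (0.1, 50.0)


class AwarenessTrial(NamedTuple):
    """One pre-test trial: executed reach ``e`` and reported direction ``i`` (deg)."""

    e: float
    i: float


@dataclass(frozen=True)
class AwarenessFit:
    """Maximum-likelihood motor/proprioceptive noise estimates for one participant."""

    sigma_m_hat: float
    sigma_p_hat: float
    shrinkage: float
    log_likelihood: float
    n_trials: int
    converged: bool


class FitError(RuntimeError):
    """Raised when the pre-test data cannot identify the noise parameters."""


def _check_sigmas(sigma_m: float, sigma_p: float) -> None:
    if sigma_m <= 0 or sigma_p <= 0:
        raise ValueError(f"noise SDs must be positive (got sigma_m={sigma_m}, sigma_p={sigma_p})")


def shrinkage_weight(sigma_m: float, sigma_p: float) -> float:
    """MAP weight k = r_p/(r_p + r_m) on the sensed direction."""
    _check_sigmas(sigma_m, sigma_p)
    sm2, sp2 = sigma_m**2, sigma_p**2
    return sm2 / (sm2 + sp2)


def map_report(s, sigma_m: float, sigma_p: float):
    """Ideal report i = k*s for sensed direction(s) ``s`` (deg)."""
    return shrinkage_weight(sigma_m, sigma_p) * np.asarray(s, dtype=float)


def trial_loglik(e, i, sigma_m: float, sigma_p: float):
    """Log likelihood (nats) of trial(s) d = (e, i) at the given noise SDs.

    Vectorized over ``e`` and ``i``; returns a scalar for scalar inputs.
    """
    _check_sigmas(sigma_m, sigma_p)
    e = np.asarray(e, dtype=float)
    i = np.asarray(i, dtype=float)
    k = shrinkage_weight(sigma_m, sigma_p)
    var_e = sigma_m**2
    var_i = (k * sigma_p) ** 2
    ll = (
        -0.5 * (_LOG_2PI + np.log(var_e)) - e**2 / (2.0 * var_e)
        - 0.5 * (_LOG_2PI + np.log(var_i)) - (i - k * e) ** 2 / (2.0 * var_i)
    )
    return ll if ll.ndim else float(ll)


def total_loglik(e, i, sigma_m: float, sigma_p: float) -> float:
    """Summed log likelihood across independent trials."""
    return float(np.sum(trial_loglik(e, i, sigma_m, sigma_p)))


def _as_arrays(trials) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of (e, i) pairs / AwarenessTrials, or a pair of arrays."""
    if isinstance(trials, tuple) and len(trials) == 2 and np.ndim(trials[0]) >= 1:
        e, i = (np.asarray(a, dtype=float) for a in trials)
    else:
        arr = np.asarray([(t.e, t.i) if isinstance(t, AwarenessTrial) else tuple(t) for t in trials], dtype=float)
        if arr.size == 0:
            return np.empty(0), np.empty(0)
        e, i = arr[:, 0], arr[:, 1]
    if e.shape != i.shape:
        raise ValueError("endpoint and report arrays must have equal length")
    return e, i


def fit_awareness(trials, reports=None) -> AwarenessFit:
    """Maximum-likelihood (sigma_m, sigma_p) from pre-test (endpoint, report) pairs.

    Parameters
    ----------
    trials
        Either a sequence of ``AwarenessTrial``/(e, i) pairs, or an array of
        endpoints ``e`` when ``reports`` is given separately.
    reports
        Reported directions ``i``, if ``trials`` holds the endpoints.

    The objective is log-parameterized (fit log sigma) and maximized by a
    Nelder-Mead refinement seeded from the best node of an 11x11 log-spaced
    grid over [0.5, 30] deg; bounds are enforced by the transform plus a hard
    box of [0.1, 50] deg.
    """
    if reports is not None:
        e, i = _as_arrays((np.atleast_1d(trials), np.atleast_1d(reports)))
    else:
        e, i = _as_arrays(trials)
    if e.size < 2:
        raise FitError("need at least 2 trials to fit two noise parameters")
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(i))):
        raise FitError("endpoints and reports must be finite")
    if np.ptp(e) == 0:
        raise FitError(
            "all reach endpoints are identical: motor noise is unidentifiable "
            "(zero endpoint variance)"
        )

    def neg_ll(log_sigma: np.ndarray) -> float:
        sm, sp = np.exp(log_sigma)
        return -total_loglik(e, i, sm, sp)

    grid = np.log(np.geomspace(*GRID_RANGE, GRID_SIZE))
    nodes = [(a, b) for a in grid for b in grid]
    values = [neg_ll(np.array(n)) for n in nodes]
    x0 = np.array(nodes[int(np.argmin(values))])

    log_bounds = [(np.log(SIGMA_BOUNDS[0]), np.log(SIGMA_BOUNDS[1]))] * 2
    res = minimize(
        neg_ll,
        x0,
        method="Nelder-Mead",
        bounds=log_bounds,
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    sm_hat, sp_hat = np.exp(res.x)
    return AwarenessFit(
        sigma_m_hat=float(sm_hat),
        sigma_p_hat=float(sp_hat),
        shrinkage=float(shrinkage_weight(sm_hat, sp_hat)),
        log_likelihood=float(-res.fun),
        n_trials=int(e.size),
        converged=bool(res.success),
    )
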