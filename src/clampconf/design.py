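"""Experimental schedule: session layout and the sinusoidal error-clamp sequence.

A session is a fixed-length block of reaching trials toward a single target
straight ahead of the participant (0 deg).  Cursor feedback is error-clamped:
its direction on trial ``t`` is set by the experimenter to

    clamp(t) = sign * A * sin(2*pi*(t - 1) / P)

for 1-based trial index ``t``, amplitude ``A`` (deg) and cycle length ``P``
(trials), so the first trial is always exactly 0 deg.  Two task variants share
the schedule and differ only in the confidence wager: the *sensorimotor* task
(arc centered on the target, 1-40 deg) and the *motor-awareness* task (arc
centered on the reported hand direction, 1-20 deg).

Angle convention: positive angles are counter-clockwise from the straight-ahead
target; all angles are stored in degrees (radians appear only inside
trigonometric internals).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Task",
    "SessionDesign",
    "ConfigurationError",
    "make_clamp_sequence",
    "design_to_config",
    "design_from_config",
]


class ConfigurationError(ValueError):
    """An invalid design, observer, or analysis configuration."""


class Task(str, Enum):
    SENSORIMOTOR = "sensorimotor"
    MOTOR_AWARENESS = "motor_awareness"


# Wager-bound constants by task: (max arc at zero points, initial-arc range hi).
_WAGER_MAX_ARC = {Task.SENSORIMOTOR: 40.0, Task.MOTOR_AWARENESS: 20.0}


@dataclass(frozen=True)
class SessionDesign:
    """Experimenter-controlled schedule for one session.

    Parameters
    ----------
    n_trials : int
        Trials per session; must be a positive multiple of ``trials_per_cycle``.
    trials_per_cycle : int
        Error-clamp cycle length in trials.
    clamp_amplitude : float
        Peak clamp excursion in degrees (>= 0).
    task : Task or str
        Which confidence wager the session uses.
    clamp_sign : int
        +1 (default) for a counter-clockwise first excursion, -1 to flip.
    """

    n_trials: int = 240
    trials_per_cycle: int = 20
    clamp_amplitude: float = 10.0
    task: Task = Task.SENSORIMOTOR
    clamp_sign: int = 1

    # Fixed across the experiment.
    target_direction: float = 0.0
    wager_full_points_arc: float = 2.0
    wager_max_points: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", Task(self.task))
        if self.trials_per_cycle <= 0:
            raise ConfigurationError("trials_per_cycle must be positive")
        if self.n_trials <= 0 or self.n_trials % self.trials_per_cycle != 0:
            raise ConfigurationError(
                "n_trials must be a positive multiple of trials_per_cycle "
                f"(got n_trials={self.n_trials}, trials_per_cycle={self.trials_per_cycle})"
            )
        if self.clamp_amplitude < 0:
            raise ConfigurationError("clamp_amplitude must be >= 0")
        if self.clamp_sign not in (1, -1):
            raise ConfigurationError("clamp_sign must be +1 or -1")
        if self.wager_full_points_arc >= self.wager_max_arc:
            raise ConfigurationError(
                "wager_full_points_arc must be below wager_max_arc"
            )

    @property
    def cycles_per_session(self) -> int:
        return self.n_trials // self.trials_per_cycle

    @property
    def wager_max_arc(self) -> float:
        """Arc subtense (deg) at and beyond which a captured trial earns 0 points."""
        return _WAGER_MAX_ARC[self.task]

    @property
    def initial_arc_range(self) -> tuple[float, float]:
        """Uniform range (deg) the starting arc subtense is drawn from."""
        return (1.0, self.wager_max_arc)


def make_clamp_sequence(design: SessionDesign) -> np.ndarray:
    """Error-clamp direction (deg) for every trial of the session.

    The sequence is built from one exactly-tiled cycle so that
    ``clamp[t] == clamp[t + P]`` bit-for-bit and trial 1 is exactly 0 deg.
    """
    p = design.trials_per_cycle
    phase = 2.0 * np.pi * np.arange(p) / p
    cycle = design.clamp_sign * design.clamp_amplitude * np.sin(phase)
    cycle[0] = 0.0  # sin(0) is exact already; keep the contract explicit
    return np.tile(cycle, design.cycles_per_session)


# -- plain-text (YAML key: value) serialization ------------------------------

_CONFIG_KEYS = ("n_trials", "trials_per_cycle", "clamp_amplitude", "task", "clamp_sign")


def design_to_config(design: SessionDesign, path: str | Path | None = None) -> str:
    """Serialize a design to a ``key: value`` text block (optionally to a file)."""
    d = asdict(design)
    payload = {k: (d[k].value if isinstance(d[k], Task) else d[k]) for k in _CONFIG_KEYS}
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def design_from_config(source: str | Path) -> SessionDesign:
    """Load a design from a ``key: value`` text block or a file path."""
    if isinstance(source, Path) or ("\n" not in str(source) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"design config must be a key: value mapping, got {type(data)}")
    unknown = set(data) - set(_CONFIG_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown design config keys: {sorted(unknown)}")
    return SessionDesign(**data)
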