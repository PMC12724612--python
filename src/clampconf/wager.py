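"""Points-wager scoring of confidence arcs.

The participant sets the subtense of a confidence arc; points are earned only
when the arc encloses the true reach direction ("captured"), and decrease
linearly with arc size from ``max_points`` at ``full_points_arc`` or smaller
down to zero at ``zero_points_arc`` or larger.  The arc extends equidistantly
to both sides of its center (the target in the sensorimotor task, the reported
direction in the motor-awareness task), so enclosure uses the half-subtense
and is boundary-inclusive.

Angles must lie within +-180 deg of the target; directions in practice stay
within +-90 deg and no angular wrap-around is applied.  Points are real-valued
(no rounding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import SessionDesign, Task

__all__ = ["WagerRule", "capture", "score_trial", "session_score"]


@dataclass(frozen=True)
class WagerRule:
    """Linear points schedule and arc center convention for one task."""

    max_points: float = 10.0
    full_points_arc: float = 2.0
    zero_points_arc: float = 40.0
    center_mode: str = "target"  # or "report"

    def __post_init__(self) -> None:
        if self.full_points_arc >= self.zero_points_arc:
            raise ValueError("full_points_arc must be below zero_points_arc")
        if self.max_points <= 0:
            raise ValueError("max_points must be positive")
        if self.center_mode not in ("target", "report"):
            raise ValueError(f"unknown center_mode {self.center_mode!r}")

    @classmethod
    def for_design(cls, design: SessionDesign) -> "WagerRule":
        return cls(
            max_points=design.wager_max_points,
            full_points_arc=design.wager_full_points_arc,
            zero_points_arc=design.wager_max_arc,
            center_mode="target" if design.task is Task.SENSORIMOTOR else "report",
        )


def _check_angles(*angles) -> None:
    for a in angles:
        if np.any(np.abs(a) > 180.0):
            raise ValueError("directions beyond +-180 deg of the target are not meaningful here")


def capture(center, arc_size, reach_dir):
    """True where the arc of full subtense ``arc_size`` centered on ``center``
    encloses ``reach_dir`` (boundary inclusive).  Vectorized; degrees."""
    center, arc_size, reach_dir = (np.asarray(x, dtype=float) for x in (center, arc_size, reach_dir))
    if np.any(arc_size <= 0):
        raise ValueError("arc_size must be positive")
    _check_angles(center, reach_dir)
    out = np.abs(reach_dir - center) <= arc_size / 2.0
    return out if out.ndim else bool(out)


def score_trial(rule: WagerRule, center, arc_size, reach_dir):
    """Points for trial(s): 0 if not captured, else linear in arc size.

    Captured arcs at or below ``full_points_arc`` earn ``max_points``; points
    fall linearly to 0 at ``zero_points_arc`` and stay 0 beyond.
    """
    captured = capture(center, arc_size, reach_dir)
    frac = (rule.zero_points_arc - np.asarray(arc_size, dtype=float)) / (
        rule.zero_points_arc - rule.full_points_arc
    )
    pts = np.asarray(captured, dtype=float) * rule.max_points * np.clip(frac, 0.0, 1.0)
    return pts if pts.ndim else float(pts)


def session_score(session, rule: WagerRule) -> tuple[float, float]:
    """(total points, capture rate in %) over a complete session table."""
    center = session["report_dir"] if rule.center_mode == "report" else np.zeros(len(session))
    cap = capture(center, session["confidence_arc"], session["reach_dir"])
    pts = score_trial(rule, center, session["confidence_arc"], session["reach_dir"])
    return float(np.sum(pts)), float(100.0 * np.mean(cap))
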