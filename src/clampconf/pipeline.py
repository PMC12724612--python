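"""Session I/O, engagement and correlation checks, group comparison, and the
end-to-end cohort pipeline (simulate -> fit -> analyze -> summarize).

Sessions travel as plain CSV with a fixed header (degrees throughout); a
cohort run writes one session file per participant per task plus a manifest
of true generating parameters, and produces a per-participant summary table
of spectral components, wager outcomes, and confidence correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .awareness import AwarenessFit, fit_awareness
from .design import ConfigurationError, SessionDesign, Task
from .observer import ObserverParams, simulate_cohort, simulate_pretest
from .spectral import ALPHA, SessionSpectra, analyze_signals
from .wager import WagerRule, session_score

__all__ = [
    "SchemaError",
    "CorrelationResult",
    "EngagementResult",
    "read_session",
    "write_session",
    "engagement_check",
    "mismatch_correlation",
    "report_error_correlation",
    "group_compare",
    "default_config",
    "load_config",
    "reproduce",
]

logger = logging.getLogger("clampconf")

#: Required columns of a session CSV, in canonical order.  report_dir is
#: required only for motor-awareness sessions; latent columns (adapt_state,
#: sensed_dir) exist only in synthetic data and are optional on read.
SESSION_COLUMNS = (
    "trial",
    "clamp_dir",
    "reach_dir",
    "initial_arc",
    "confidence_arc",
    "captured",
    "points",
)


class SchemaError(ValueError):
    """A session table violating the documented CSV schema."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    degenerate: bool = False  # zero-variance input; r reported as 0 by convention


@dataclass(frozen=True)
class EngagementResult:
    r: float
    p: float
    flagged: bool


def write_session(session: pd.DataFrame, path: str | Path) -> Path:
    """Write a session table to CSV (lossless float round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    session.to_csv(path, index=False)
    logger.info("wrote session with %d trials to %s", len(session), path)
    return path


def read_session(path: str | Path, task: Task | str | None = None) -> pd.DataFrame:
    """Read and validate a session CSV.

    Checks the documented header column by column; unknown extra columns are
    preserved with a warning.  ``task`` adds the task-specific requirement
    (report_dir for motor-awareness sessions).
    """
    df = pd.read_csv(path)
    required = list(SESSION_COLUMNS)
    if task is not None and Task(task) is Task.MOTOR_AWARENESS:
        required.append("report_dir")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    known = set(SESSION_COLUMNS) | {"report_dir", "adapt_state", "sensed_dir"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: preserving unknown column(s) %s", path, extra)
    trials = df["trial"].to_numpy()
    if not np.array_equal(trials, np.arange(1, len(df) + 1)):
        raise SchemaError(f"{path}: trial column must run 1..n with no gaps")
    if np.any(df["confidence_arc"].to_numpy() <= 0):
        raise SchemaError(f"{path}: confidence_arc must be strictly positive")
    return df


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(r=0.0, p=1.0, degenerate=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p))


def engagement_check(initial_arcs, final_arcs, alpha: float = 0.05) -> EngagementResult:
    """Did the participant actually adjust the randomly-seeded arc?

    The starting subtense is random, so an engaged participant's final arcs
    should be uncorrelated with it.  Flagged when the correlation is
    significant at ``alpha``, or when the final arcs never changed (constant,
    or identical to the initial ones).
    """
    initial = np.asarray(initial_arcs, dtype=float)
    final = np.asarray(final_arcs, dtype=float)
    if initial.shape != final.shape or initial.size < 10:
        raise ValueError("need equal-length arc series with at least 10 trials")
    res = _pearson(initial, final)
    untouched = bool(np.array_equal(initial, final) or np.ptp(final) == 0)
    flagged = untouched or (not res.degenerate and res.p < alpha)
    if flagged:
        logger.warning("engagement check flagged (r=%.3f, p=%.3g, untouched=%s)", res.r, res.p, untouched)
    return EngagementResult(r=res.r, p=res.p, flagged=flagged)


def mismatch_correlation(session: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of the confidence arc with |clamp - reach|.

    A positive r means lower confidence (wider arcs) on trials with a larger
    visuo-proprioceptive mismatch between cursor and hand.
    """
    for col in ("clamp_dir", "reach_dir", "confidence_arc"):
        if col not in session.columns:
            raise SchemaError(f"mismatch_correlation needs column {col!r}")
    mismatch = np.abs(session["clamp_dir"].to_numpy() - session["reach_dir"].to_numpy())
    return _pearson(session["confidence_arc"].to_numpy(), mismatch)


def report_error_correlation(session: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of the confidence arc with |report - reach| —
    the distance the points wager actually depends on (motor-awareness task)."""
    if "report_dir" not in session.columns:
        raise SchemaError("report_error_correlation needs a motor-awareness session with report_dir")
    err = np.abs(session["report_dir"].to_numpy() - session["reach_dir"].to_numpy())
    return _pearson(session["confidence_arc"].to_numpy(), err)


def group_compare(values_a, values_b) -> tuple[float, int, float]:
    """Two-sample pooled-variance Student t test: (t, df, p), df = n_a + n_b - 2."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), int(a.size + b.size - 2), float(p)


# -- end-to-end cohort pipeline ----------------------------------------------


def default_config() -> dict:
    """Single source of design + observer + analysis parameters."""
    return {
        "design": {
            "n_trials": 240,
            "trials_per_cycle": 20,
            "clamp_amplitude": 10.0,
            "clamp_sign": 1,
        },
        "observer": {
            "sigma_m": 4.0,
            "sigma_p": 7.0,
            "retention": 0.5,
            "learning_rate": 0.5468,
            "report_policy": "weighted_combination",  # motor-awareness sessions
            "report_weight": 0.5,
            "report_noise_sd": 2.0,
            "confidence_policy": "mismatch_driven",
            "conf_baseline": 6.0,
            "conf_gain": 0.5,
            "conf_noise_sd": 2.0,
        },
        "cohort": {"n_participants": 20, "pretest_trials": 80},
        "analysis": {"n_shuffles": 100_000, "alpha": ALPHA},
    }


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config, filling unspecified keys from the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    for section, values in user.items():
        if section not in cfg:
            raise ConfigurationError(f"{path}: unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigurationError(f"{path}: section {section!r} must be a mapping")
        unknown = set(values) - set(cfg[section])
        if unknown:
            raise ConfigurationError(f"{path}: unknown keys in {section!r}: {sorted(unknown)}")
        cfg[section].update(values)
    return cfg


def _summary_row(
    pid: int,
    task: Task,
    spectra: SessionSpectra,
    total: float,
    rate: float,
    mism: CorrelationResult,
    rep_err: Optional[CorrelationResult],
    engagement: EngagementResult,
) -> dict:
    row = {
        "participant": pid,
        "task": task.value,
        "reach_amplitude": spectra.reach.amplitude,
        "reach_lag": spectra.reach.trial_lag,
        "reach_significant": spectra.reach.significant,
        "conf_amplitude": spectra.confidence.amplitude,
        "conf_lag": spectra.confidence.trial_lag,
        "conf_significant": spectra.confidence.significant,
        "conf_mean_arc": spectra.confidence_mean,
        "total_points": total,
        "capture_rate": rate,
        "mismatch_r": mism.r,
        "mismatch_p": mism.p,
        "engagement_flagged": engagement.flagged,
    }
    if spectra.report is not None:
        row.update(
            report_amplitude=spectra.report.amplitude,
            report_lag=spectra.report.trial_lag,
            report_significant=spectra.report.significant,
        )
    if rep_err is not None:
        row.update(report_error_r=rep_err.r, report_error_p=rep_err.p)
    return row


def reproduce(
    config: dict | str | Path | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full study pipeline on a synthetic cohort.

    For each task, simulates the cohort, runs the spectral analysis with
    permutation tests, scores the wager, and computes the confidence
    correlations; each participant also gets a simulated pre-test fitted with
    the awareness model.  Returns (summary table, awareness-fit table); with
    ``out_dir`` set, also writes session CSVs, the cohort manifest, and both
    tables.  Deterministic for a fixed seed and config.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    seed = 0 if seed is None else seed
    logger.info("reproduce: seed=%d", seed)
    obs = dict(cfg["observer"])
    report_policy = obs.pop("report_policy")
    n_shuffles = int(cfg["analysis"]["n_shuffles"])
    alpha = float(cfg["analysis"]["alpha"])
    n_participants = int(cfg["cohort"]["n_participants"])
    pretest_trials = int(cfg["cohort"]["pretest_trials"])
    out = Path(out_dir) if out_dir is not None else None

    summary_rows: list[dict] = []
    fit_rows: list[dict] = []
    manifests: list[pd.DataFrame] = []
    ss = np.random.SeedSequence(seed)
    task_seeds = {t: int(s.generate_state(1, dtype=np.uint32)[0]) for t, s in zip(Task, ss.spawn(2))}
    analysis_root = np.random.default_rng(ss.spawn(1)[0])
    pretest_rng = np.random.default_rng(ss.spawn(1)[0])

    for task in Task:
        design = SessionDesign(task=task, **cfg["design"])
        params = ObserverParams(
            report_policy=report_policy if task is Task.MOTOR_AWARENESS else None, **obs
        )
        sessions, manifest = simulate_cohort(n_participants, params, design, seed=task_seeds[task])
        manifests.append(manifest)
        rule = WagerRule.for_design(design)
        for pid, session in enumerate(sessions, start=1):
            spectra = analyze_signals(session, design, n_shuffles=n_shuffles, rng=analysis_root, alpha=alpha)
            total, rate = session_score(session, rule)
            mism = mismatch_correlation(session)
            rep_err = report_error_correlation(session) if task is Task.MOTOR_AWARENESS else None
            engagement = engagement_check(session["initial_arc"], session["confidence_arc"])
            summary_rows.append(
                _summary_row(pid, task, spectra, total, rate, mism, rep_err, engagement)
            )
            if out is not None:
                write_session(session, out / f"participant{pid:02d}_{task.value}.csv")

    for pid in range(1, n_participants + 1):
        pretest = simulate_pretest(obs["sigma_m"], obs["sigma_p"], pretest_trials, pretest_rng)
        fit = fit_awareness(pretest["reach_dir"].to_numpy(), pretest["report_dir"].to_numpy())
        fit_rows.append({"participant": pid, **fit.__dict__})

    summary = pd.DataFrame(summary_rows)
    fits = pd.DataFrame(fit_rows)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        pd.concat(manifests, ignore_index=True).to_csv(out / "manifest.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        fits.to_csv(out / "awareness_fits.csv", index=False)
        logger.info("reproduce: wrote outputs under %s", out)
    return summary, fits
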