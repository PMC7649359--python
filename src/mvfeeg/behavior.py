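"""Behavioral measures: pedal latency time and embodiment-questionnaire scores.

Latency time (LT) is the interval from the go cue to the pedal press that
signals perceived embodiment; trials without a press carry a missing LT and
are excluded from aggregation. Questionnaire ratings are integers on the
-5..+5 Likert scale across eight statements in four subscales (location,
ownership, agency, deafference), one rating per subject, condition and
statement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import EQ_STATEMENTS, EQ_SUBSCALES


def compute_latency(events: pd.DataFrame, task_dur_s: float = 10.0) -> pd.DataFrame:
    """Per-trial latency table from the event log.

    Returns one row per trial with ``lt_s = t_pedal_s - t_go_s`` (NaN when
    the subject did not pedal). Latencies outside (0, task duration] or a
    pedal without a matching go cue raise.
    """
    required = {"subject", "run", "trial", "condition", "t_go_s", "t_pedal_s"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event log missing columns: {sorted(missing)}")
    out = events[sorted(required, key=list(events.columns).index)].copy()
    go = out["t_go_s"].to_numpy(dtype=float)
    pedal = out["t_pedal_s"].to_numpy(dtype=float)
    if (np.isnan(go) & ~np.isnan(pedal)).any():
        raise ValueError("pedal event without a matching go cue")
    lt = pedal - go
    bad = np.isfinite(lt) & ((lt <= 0) | (lt > task_dur_s))
    if bad.any():
        raise ValueError(f"{int(bad.sum())} latencies outside (0, {task_dur_s}] s")
    out["lt_s"] = lt
    return out


def summarize_latency(
    behavior: pd.DataFrame, subject_mean_first: bool = True
) -> pd.DataFrame:
    """Condition-wise LT mean and SD over non-missing trials.

    By default each subject contributes one value (their trial-mean LT) per
    condition, matching the subject-as-random-factor design; trial pooling
    across subjects is available with ``subject_mean_first=False``.
    """
    b = behavior.dropna(subset=["lt_s"])
    if subject_mean_first:
        per_subj = b.groupby(["condition", "subject"], sort=False)["lt_s"].mean()
        g = per_subj.groupby("condition", sort=False)
        out = g.agg(mean_s="mean", sd_s="std", n="count").reset_index()
    else:
        g = b.groupby("condition", sort=False)["lt_s"]
        out = g.agg(mean_s="mean", sd_s="std", n="count").reset_index()
    return out


def latency_matrix(behavior: pd.DataFrame, conditions: tuple[str, ...]) -> np.ndarray:
    """Subjects x conditions matrix of per-subject mean LT (stats input)."""
    per_subj = (
        behavior.dropna(subset=["lt_s"])
        .groupby(["subject", "condition"], sort=False)["lt_s"].mean()
        .unstack("condition")
    )
    missing = [c for c in conditions if c not in per_subj.columns]
    if missing or per_subj[list(conditions)].isna().any().any():
        raise ValueError("some subject x condition cells have no pedaled trials")
    return per_subj[list(conditions)].sort_index().to_numpy()


def _validate_eq(eq: pd.DataFrame) -> None:
    r = eq["rating"].to_numpy()
    if not np.array_equal(r, r.astype(int)) or (np.abs(r) > 5).any():
        raise ValueError("ratings must be integers in [-5, +5]")
    unknown = set(eq["statement_id"]) - set(EQ_STATEMENTS)
    if unknown:
        raise ValueError(f"unknown statements: {sorted(unknown)}")
    dup = eq.duplicated(subset=["subject", "condition", "statement_id"])
    if dup.any():
        raise ValueError("duplicate (subject, condition, statement) rows")


def score_eq(eq: pd.DataFrame) -> pd.DataFrame:
    """Per-(condition, statement) summary: median, quartiles, IQR, subscale.

    The input must be a complete long table (subject, condition,
    statement_id, rating); paired per-subject structure for the Friedman and
    Wilcoxon tests is available via :func:`eq_matrix`.
    """
    _validate_eq(eq)
    g = eq.groupby(["condition", "statement_id"], sort=False)["rating"]
    out = g.agg(
        median="median",
        q25=lambda v: float(np.percentile(v, 25)),
        q75=lambda v: float(np.percentile(v, 75)),
        n="count",
    ).reset_index()
    out["iqr"] = out["q75"] - out["q25"]
    out["subscale"] = out["statement_id"].map(EQ_SUBSCALES)
    return out


def eq_matrix(eq: pd.DataFrame, statement_id: str, conditions: tuple[str, ...]) -> np.ndarray:
    """Subjects x conditions rating matrix for one statement (stats input)."""
    _validate_eq(eq)
    wide = (
        eq[eq["statement_id"] == statement_id]
        .pivot(index="subject", columns="condition", values="rating")
    )
    if wide[list(conditions)].isna().any().any():
        raise ValueError(f"incomplete ratings for statement {statement_id!r}")
    return wide[list(conditions)].sort_index().to_numpy(dtype=float)
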