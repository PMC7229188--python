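"""Signal-detection scoring of n-back trial outcomes.

Performance on each scored cell (subject x session x condition x modality)
is summarized by d' = Z(H) - Z(F), where H is the hit rate over targets, F
the false-alarm rate over non-targets, and Z the inverse standard-normal
CDF. Rates of exactly 0 or 1 are replaced by 0.01 / 0.99 so d' stays
finite. The two stimulus modalities (auditory, visuospatial) are then
averaged into a single cumulative d' per subject x session x condition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hit_rate",
    "false_alarm_rate",
    "clamp_rate",
    "dprime",
    "subject_dprime",
    "percent_change",
    "group_improvement",
]

SESSIONS = ("Naive", "Early", "Middle", "Late")
CONDITIONS = ("1-back", "2-back")
MODALITIES = ("auditory", "visuospatial")

_COUNT_COLS = ("hits", "misses", "false_alarms", "correct_rejections")


def hit_rate(hits: int, misses: int) -> float:
    """H = hits / (hits + misses)."""
    if hits < 0 or misses < 0:
        raise ValueError("counts must be nonnegative")
    total = hits + misses
    if total == 0:
        raise ValueError("hit rate undefined: no target trials")
    return hits / total


def false_alarm_rate(false_alarms: int, correct_rejections: int) -> float:
    """F = false alarms / (false alarms + correct rejections)."""
    if false_alarms < 0 or correct_rejections < 0:
        raise ValueError("counts must be nonnegative")
    total = false_alarms + correct_rejections
    if total == 0:
        raise ValueError("false-alarm rate undefined: no non-target trials")
    return false_alarms / total


def clamp_rate(rate: float) -> float:
    """Replace exact 0 by 0.01 and exact 1 by 0.99; leave the rest alone.

    Only the degenerate endpoints are modified (not a continuous
    correction), so clamping is idempotent.
    """
    if not 0 <= rate <= 1:
        raise ValueError(f"rate {rate} outside [0, 1]")
    if rate == 0:
        return 0.01
    if rate == 1:
        return 0.99
    return float(rate)


def dprime(H: float, F: float) -> float:
    """d' = Z(H) - Z(F) with Z the standard-normal quantile function."""
    for r in (H, F):
        if not 0 < r < 1:
            raise ValueError(
                f"rate {r} must lie strictly in (0, 1); clamp first")
    return float(stats.norm.ppf(H) - stats.norm.ppf(F))


def _cell_dprime(row: pd.Series) -> tuple:
    H = clamp_rate(hit_rate(row["hits"], row["misses"]))
    F = clamp_rate(false_alarm_rate(row["false_alarms"],
                                    row["correct_rejections"]))
    return H, F, dprime(H, F)


def subject_dprime(trials: pd.DataFrame,
                   modalities=MODALITIES) -> pd.DataFrame:
    """Score a trial table into per-cell d' and the cross-modality average.

    ``trials`` needs columns subject, session, condition, modality and the
    four outcome counts. Returns one row per (subject, session, condition)
    with per-modality d' columns (``dprime_<modality>``), per-modality
    clamped rates, and ``dprime`` = arithmetic mean over modalities.
    """
    missing = [c for c in ("subject", "session", "condition", "modality",
                           *_COUNT_COLS) if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")

    scored = trials.copy()
    scored[["H", "F", "dprime"]] = scored.apply(
        lambda row: pd.Series(_cell_dprime(row)), axis=1)

    out_rows = []
    for (subj, ses, cond), cell in scored.groupby(
            ["subject", "session", "condition"], sort=False):
        row = {"subject": subj, "session": ses, "condition": cond}
        for mod in modalities:
            sub = cell[cell["modality"] == mod]
            if len(sub) != 1:
                raise ValueError(
                    "expected exactly one row for "
                    f"(subject={subj!r}, session={ses!r}, condition={cond!r}, "
                    f"modality={mod!r}); found {len(sub)}")
            row[f"H_{mod}"] = float(sub["H"].iloc[0])
            row[f"F_{mod}"] = float(sub["F"].iloc[0])
            row[f"dprime_{mod}"] = float(sub["dprime"].iloc[0])
        row["dprime"] = float(
            np.mean([row[f"dprime_{m}"] for m in modalities]))
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def percent_change(before: float, after: float) -> float:
    """100 * (after - before) / before."""
    if before == 0:
        raise ValueError("percent change undefined for zero baseline")
    return 100.0 * (after - before) / before


def group_improvement(dprimes: pd.DataFrame, condition: str,
                      before: str = "Naive", after: str = "Late",
                      per_subject: bool = False) -> float:
    """Group-level percent d' improvement between two sessions.

    Default aggregation is the percent change of the group-mean d'
    (before -> after). ``per_subject=True`` instead averages each subject's
    own percent change; both aggregations are exposed because group
    summaries of relative change are not unique.
    """
    sel = dprimes[dprimes["condition"] == condition]
    pivot = sel.pivot_table(index="subject", columns="session",
                            values="dprime")
    for ses in (before, after):
        if ses not in pivot.columns:
            raise ValueError(f"session {ses!r} absent from d' table")
    pivot = pivot.dropna(subset=[before, after])
    if pivot.empty:
        raise ValueError("no subjects with both sessions present")
    if per_subject:
        return float(np.mean([percent_change(b, a) for b, a in
                              zip(pivot[before], pivot[after])]))
    return percent_change(float(pivot[before].mean()),
                          float(pivot[after].mean()))
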