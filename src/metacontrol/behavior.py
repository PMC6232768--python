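"""Behavioral summaries, performance ratio, adaptability score, median split.

The composite behavioral statistic is the adaptability score

    score = (Acc_easy / RT_easy) - (Acc_hard / RT_hard)

with accuracy in percent (misses count as incorrect) and hit RT the mean
reaction time of correct responses in ms, so each task's performance ratio is
in %/ms and larger scores mean larger easy-over-hard performance advantages.
Subjects are split into "low" and "high" adaptability groups at the cohort
median of the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehavioralSummary", "AdaptabilityResult", "summarize_behavior",
    "performance_ratio", "adaptability_score", "median_split",
    "score_cohort",
]


@dataclass(frozen=True)
class BehavioralSummary:
    """Per subject x task counts, accuracy (%) and hit RT (ms).

    ``hit_rt_ms`` is NaN when the subject produced no correct response in the
    task (flagged via ``valid``).
    """

    subject: object
    task: str
    n_hits: int
    n_errors: int
    n_misses: int
    accuracy_pct: float
    hit_rt_ms: float

    @property
    def n_trials(self) -> int:
        return self.n_hits + self.n_errors + self.n_misses

    @property
    def valid(self) -> bool:
        return self.n_hits > 0


@dataclass(frozen=True)
class AdaptabilityResult:
    subject: object
    ratio_easy: float
    ratio_hard: float
    score: float
    group: str | None = None


def summarize_behavior(trials: pd.DataFrame) -> list[BehavioralSummary]:
    """One summary per subject x task.

    Misses are counted as incorrect in the accuracy denominator; the hit RT
    averages correct trials only.
    """
    req = {"subject", "task", "correct", "rt_ms", "miss"}
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    out = []
    for (subj, task), d in trials.groupby(["subject", "task"], sort=True):
        correct = d["correct"].to_numpy(bool)
        miss = d["miss"].to_numpy(bool)
        if (correct & miss).any():
            raise ValueError("a missed trial cannot be correct")
        n_hits = int(correct.sum())
        n_miss = int(miss.sum())
        n_err = len(d) - n_hits - n_miss
        acc = 100.0 * n_hits / len(d)
        hit_rt = float(d.loc[d["correct"], "rt_ms"].mean()) if n_hits else np.nan
        out.append(BehavioralSummary(subj, task, n_hits, n_err, n_miss,
                                     acc, hit_rt))
    return out


def performance_ratio(summary: BehavioralSummary) -> float:
    """Accuracy (%) divided by hit RT (ms); larger is better."""
    if not summary.valid or not summary.hit_rt_ms > 0:
        raise ValueError(
            f"performance ratio undefined for subject {summary.subject!r} "
            f"({summary.task}): no correct responses")
    return summary.accuracy_pct / summary.hit_rt_ms


def adaptability_score(easy: BehavioralSummary, hard: BehavioralSummary) -> float:
    """Easy-task performance ratio minus hard-task performance ratio."""
    if easy.subject != hard.subject:
        raise ValueError("summaries belong to different subjects")
    if easy.task == hard.task:
        raise ValueError("need one easy and one hard summary")
    return performance_ratio(easy) - performance_ratio(hard)


def median_split(scores: pd.Series) -> pd.Series:
    """Assign "high" to scores strictly above the cohort median, else "low".

    Deterministic tie rule: the median subject (and any subject tied with the
    median) goes to the low group, so with an odd cohort the low group gets
    the extra subject.  Group sizes differ by at most 1 when scores are
    distinct.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("median split needs at least 2 subjects")
    if s.isna().any():
        raise ValueError("scores contain NaN")
    if s.nunique() == 1:
        raise ValueError("all scores identical; no split possible")
    med = s.median()
    return pd.Series(np.where(s > med, "high", "low"), index=s.index,
                     name="group")


def score_cohort(trials: pd.DataFrame, easy_task: str = "easy",
                 hard_task: str = "hard") -> pd.DataFrame:
    """Full behavioral stage: summaries -> scores -> median-split groups.

    Returns one row per subject: ratios, score, assigned group, and the
    per-task accuracy/hit-RT summaries (wide columns).
    """
    summaries = summarize_behavior(trials)
    by_subj: dict[object, dict[str, BehavioralSummary]] = {}
    for s in summaries:
        by_subj.setdefault(s.subject, {})[s.task] = s
    rows = []
    for subj, tasks in by_subj.items():
        if easy_task not in tasks or hard_task not in tasks:
            raise ValueError(f"subject {subj!r} lacks one of the two tasks")
        e, h = tasks[easy_task], tasks[hard_task]
        rows.append({
            "subject": subj,
            "ratio_easy": performance_ratio(e),
            "ratio_hard": performance_ratio(h),
            "score": adaptability_score(e, h),
            "accuracy_easy": e.accuracy_pct, "accuracy_hard": h.accuracy_pct,
            "hit_rt_easy": e.hit_rt_ms, "hit_rt_hard": h.hit_rt_ms,
        })
    df = pd.DataFrame(rows).set_index("subject")
    df["group"] = median_split(df["score"])
    return df.reset_index()
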