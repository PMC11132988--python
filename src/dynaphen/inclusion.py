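"""Study inclusion and task-specific exclusion rules.

A participant is included for a task iff they have at least six weeks of
data and no run of more than three consecutive missing weeks. Missing runs
are counted between the participant's first and last observed week
(an interrupted but continuing participation), not before entry or after
drop-out.

Task-specific rules:

* gng — participants whose study-average accuracy is below 0.55 are
  non-learners and excluded;
* lt — participants choosing the same option on strictly more than 80% of
  trials are excluded; trials with a 100% win probability are dropped
  before modelling.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data import N_WEEKS, TrialTable

__all__ = [
    "InclusionReport",
    "apply_inclusion",
    "apply_task_exclusions",
    "drop_lt_certain_trials",
    "MIN_WEEKS",
    "MAX_CONSECUTIVE_MISSING",
    "GNG_LEARNER_ACCURACY",
    "LT_ONE_SIDED_FRACTION",
]

MIN_WEEKS = 6
MAX_CONSECUTIVE_MISSING = 3
GNG_LEARNER_ACCURACY = 0.55
LT_ONE_SIDED_FRACTION = 0.80


@dataclasses.dataclass
class InclusionReport:
    """Per participant inclusion decisions for one task."""

    task: str
    df: pd.DataFrame  # participant_id, n_weeks_present, max_consecutive_missing,
    #                   included, exclusion_reason

    def included_participants(self) -> list[str]:
        return sorted(self.df.loc[self.df["included"], "participant_id"])

    def reason(self, participant_id: str) -> str:
        row = self.df.loc[self.df["participant_id"] == participant_id]
        if row.empty:
            raise KeyError(participant_id)
        return row["exclusion_reason"].iloc[0]


def _max_missing_run(weeks_present: set[int]) -> int:
    run = best = 0
    for w in range(min(weeks_present), max(weeks_present) + 1):
        if w in weeks_present:
            run = 0
        else:
            run += 1
            best = max(best, run)
    return best


def apply_inclusion(trials: TrialTable) -> InclusionReport:
    """Weeks-present / gap rule. Idempotent and order-invariant over rows."""
    if len(trials) == 0:
        raise ValueError("empty trial table")
    rows = []
    for pid, g in trials.df.groupby("participant_id", sort=True):
        weeks = set(int(w) for w in g["week"].unique())
        gap = _max_missing_run(weeks)
        if len(weeks) < MIN_WEEKS:
            reason = "too_few_weeks"
        elif gap > MAX_CONSECUTIVE_MISSING:
            reason = "gap_too_long"
        else:
            reason = "none"
        rows.append(
            dict(
                participant_id=pid,
                n_weeks_present=len(weeks),
                max_consecutive_missing=gap,
                included=reason == "none",
                exclusion_reason=reason,
            )
        )
    return InclusionReport(task=trials.task, df=pd.DataFrame(rows))


def apply_task_exclusions(trials: TrialTable) -> InclusionReport:
    """gng non-learner and lt one-sided-chooser rules, layered on inclusion."""
    report = apply_inclusion(trials)
    if trials.task == "gng":
        acc = _gng_accuracy(trials.df)
        for i, row in report.df.iterrows():
            if row["included"] and acc.get(row["participant_id"], 1.0) < GNG_LEARNER_ACCURACY:
                report.df.loc[i, ["included", "exclusion_reason"]] = [False, "gng_nonlearner"]
    elif trials.task == "lt":
        frac = (
            trials.df.groupby("participant_id")["response"]
            .agg(lambda r: max(np.mean(r == 1), np.mean(r == 0)))
            .to_dict()
        )
        for i, row in report.df.iterrows():
            # strictly "over 80%": exactly 80% stays included
            if row["included"] and frac.get(row["participant_id"], 0.0) > LT_ONE_SIDED_FRACTION:
                report.df.loc[i, ["included", "exclusion_reason"]] = [False, "lt_one_sided"]
    return report


def _gng_accuracy(df: pd.DataFrame) -> dict[str, float]:
    correct_go = df["condition"].isin(["go_win", "go_avoid"])
    correct = np.where(correct_go, df["response"] == 1, df["response"] == 0)
    return pd.Series(correct, index=df["participant_id"]).groupby(level=0).mean().to_dict()


def drop_lt_certain_trials(trials: TrialTable) -> TrialTable:
    """Remove lottery trials with a 100% win probability before modelling."""
    if trials.task != "lt":
        raise ValueError("only applies to lt")
    return TrialTable(task="lt", df=trials.df.loc[trials.df["p"] < 1.0].reset_index(drop=True))
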