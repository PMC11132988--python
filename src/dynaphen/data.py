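"""Shared data model: per-trial tables, survey tables and phenotype matrices.

All on-disk formats are UTF-8 comma-separated CSV with ``.`` decimals and the
literal string ``NA`` for missing values. One file per task, named
``<task>.csv`` when a directory is given.

Common columns for every task table::

    participant_id, week (1..12), block (>=1), trial (>=1),
    response, rt_ms, outcome

plus task-specific stimulus/condition columns (see ``TASK_COLUMNS``).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TASKS",
    "TASK_COLUMNS",
    "TrialTable",
    "SurveyTable",
    "SchemaError",
    "ValidationError",
    "load_trials",
    "save_trials",
    "load_survey",
    "save_survey",
]

#: canonical task codes, in battery order
TASKS = ("gng", "cd", "rdm", "lt", "itc", "tab", "nc")

N_WEEKS = 12

_COMMON = ["participant_id", "week", "block", "trial", "response", "rt_ms", "outcome"]

#: task-specific columns appended after the common prefix
TASK_COLUMNS = {
    # stimulus: 0..3 within block; condition: go_win/go_avoid/nogo_win/nogo_avoid
    "gng": ["stimulus", "condition"],
    # set_size in {3,4,6,8}; d1..d8 per-item hue-difference magnitudes (deg)
    "cd": ["set_size"] + [f"d{i}" for i in range(1, 9)],
    "rdm": ["coherence"],
    # single win probability p shared by both tickets (the odds are matched)
    "lt": ["p", "risky_hi", "risky_lo", "safe_hi", "safe_lo"],
    "itc": ["amount_now", "amount_later", "delay_days"],
    # arm labels R/S; reward observed on the chosen arm
    "tab": ["arm1_label", "arm2_label", "reward"],
    "nc": ["a1", "a2"],
}

_NUMERIC = {
    "week",
    "block",
    "trial",
    "rt_ms",
    "stimulus",
    "set_size",
    "coherence",
    "p",
    "risky_hi",
    "risky_lo",
    "safe_hi",
    "safe_lo",
    "amount_now",
    "amount_later",
    "delay_days",
    "reward",
    "a1",
    "a2",
    "response",
} | {f"d{i}" for i in range(1, 9)}


class SchemaError(ValueError):
    """Header does not match the documented per-task schema."""


class ValidationError(ValueError):
    """Rows violate a table invariant; offending row numbers are listed."""


@dataclasses.dataclass
class TrialTable:
    """Long-format per-trial records for one task."""

    task: str
    df: pd.DataFrame

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")

    def __len__(self):
        return len(self.df)

    @property
    def participants(self) -> list[str]:
        return sorted(self.df["participant_id"].unique())

    def sessions(self):
        """Iterate (participant_id, week, session frame) in sorted order."""
        for (pid, week), g in self.df.groupby(["participant_id", "week"], sort=True):
            yield pid, int(week), g.sort_values(["block", "trial"])


@dataclasses.dataclass
class SurveyTable:
    """Per-session survey responses (items 1..36; item 34 is free text)."""

    df: pd.DataFrame

    def __len__(self):
        return len(self.df)


SURVEY_COLUMNS = ["participant_id", "week", "day", "item_id", "response"]
FREE_TEXT_ITEM = 34
N_SURVEY_ITEMS = 36


def columns_for(task: str) -> list[str]:
    return _COMMON + TASK_COLUMNS[task]


def _validate_trials(task: str, df: pd.DataFrame) -> None:
    problems: list[str] = []
    # row numbers reported 1-based, excluding the header line
    rows = np.arange(len(df)) + 1

    week = df["week"].to_numpy(dtype=float)
    bad = rows[(week < 1) | (week > N_WEEKS) | (week != np.round(week))]
    if bad.size:
        problems.append(f"week outside 1..{N_WEEKS} at rows {bad[:10].tolist()}")

    for col in ("block", "trial"):
        v = df[col].to_numpy(dtype=float)
        bad = rows[(v < 1) | (v != np.round(v))]
        if bad.size:
            problems.append(f"{col} < 1 at rows {bad[:10].tolist()}")

    rt = df["rt_ms"].to_numpy(dtype=float)
    bad = rows[np.isfinite(rt) & (rt < 0)]
    if bad.size:
        problems.append(f"negative rt_ms at rows {bad[:10].tolist()}")

    dup = df.duplicated(subset=["participant_id", "week", "block", "trial"], keep=False)
    if dup.any():
        problems.append(
            "duplicate (participant, week, block, trial) at rows "
            f"{rows[dup.to_numpy()][:10].tolist()}"
        )

    if problems:
        raise ValidationError(f"{task}: " + "; ".join(problems))


def _resolve(path: str | Path, task: str | None) -> Path:
    path = Path(path)
    if path.is_dir():
        if task is None:
            raise ValueError("a directory path requires a task name")
        return path / f"{task}.csv"
    return path


def load_trials(path: str | Path, task: str) -> TrialTable:
    """Load and validate one task's trial table from CSV.

    ``path`` may be a file or a directory holding ``<task>.csv``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    f = _resolve(path, task)
    if not f.exists():
        raise FileNotFoundError(f)
    df = pd.read_csv(f, na_values=["NA"], keep_default_na=False)
    expected = columns_for(task)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{task}: missing columns {missing}")
    df = df[expected].copy()
    for col in expected:
        if col in _NUMERIC:
            df[col] = pd.to_numeric(df[col], errors="raise")
    if len(df):
        _validate_trials(task, df)
    return TrialTable(task=task, df=df)


def save_trials(table: TrialTable, path: str | Path) -> Path:
    f = _resolve(path, table.task)
    f.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(f, index=False, na_rep="NA")
    return f


def load_survey(path: str | Path) -> SurveyTable:
    f = _resolve(path, "survey")
    df = pd.read_csv(f, na_values=["NA"], keep_default_na=False)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey: missing columns {missing}")
    df = df[SURVEY_COLUMNS].copy()
    for col in ("week", "day", "item_id", "response"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    dup = df.duplicated(subset=["participant_id", "week", "day", "item_id"], keep=False)
    if dup.any():
        raise ValidationError("survey: duplicate (participant, week, day, item)")
    return SurveyTable(df=df)


def save_survey(table: SurveyTable, path: str | Path) -> Path:
    f = _resolve(path, "survey")
    f.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(f, index=False, na_rep="NA")
    return f
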