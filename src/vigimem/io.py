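"""CSV table formats and validated readers/writers.

Fixed, versioned headers (missing values are empty fields):

trials        participant_id,block_index,trial_index,stimulus_digit,is_target,responded,rt
ratings       participant_id,block_index,fatigue,motivation
memory        participant_id,task,phase,item_index,outcome,rt
participants  participant_id,group,age,gender,days_since_diagnosis,
              maintenance_interval,<scale columns...>

Vigilance RTs must lie in (0, 1] seconds — the trial cadence is one second,
so a longer RT cannot belong to the trial it is recorded against.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "read_trials",
    "read_ratings",
    "read_memory",
    "read_participants",
    "write_tables",
    "read_tables",
    "TRIAL_COLUMNS",
    "RATING_COLUMNS",
    "MEMORY_COLUMNS",
    "PARTICIPANT_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant_id",
    "block_index",
    "trial_index",
    "stimulus_digit",
    "is_target",
    "responded",
    "rt",
]
RATING_COLUMNS = ["participant_id", "block_index", "fatigue", "motivation"]
MEMORY_COLUMNS = ["participant_id", "task", "phase", "item_index", "outcome", "rt"]
PARTICIPANT_COLUMNS = [
    "participant_id",
    "group",
    "age",
    "gender",
    "days_since_diagnosis",
    "maintenance_interval",
]

MEMORY_OUTCOME_VALUES = {
    "correct",
    "same_object_wrong_orientation",
    "other_error",
    "hit",
    "miss",
    "false_alarm",
    "correct_rejection",
}


class ParseError(ValueError):
    """Structured parse/validation error, carrying the offending location."""


def _require_columns(df: pd.DataFrame, required: list, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _first_bad_row(mask: np.ndarray) -> int:
    return int(np.flatnonzero(mask)[0]) + 2  # +1 for header, +1 for 1-based


def read_trials(path) -> pd.DataFrame:
    """Read and validate a vigilance trial table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRIAL_COLUMNS, path)
    try:
        df = df.astype(
            {
                "block_index": "int64",
                "trial_index": "int64",
                "stimulus_digit": "int64",
                "is_target": "bool",
                "responded": "bool",
                "rt": "float64",
            }
        )
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: bad column dtype ({exc})") from exc
    dup = df.duplicated(subset=["participant_id", "block_index", "trial_index"])
    if dup.any():
        raise ParseError(f"{path}: duplicate trial key at row {_first_bad_row(dup.to_numpy())}")
    mismatch = (df["stimulus_digit"] == 0) != df["is_target"]
    if mismatch.any():
        raise ParseError(
            f"{path}: is_target inconsistent with stimulus_digit at row "
            f"{_first_bad_row(mismatch.to_numpy())}"
        )
    rt = df["rt"].to_numpy()
    has_rt = ~np.isnan(rt)
    bad_rt = has_rt & ((rt <= 0) | (rt > 1.0))
    if bad_rt.any():
        raise ParseError(
            f"{path}: rt outside (0, 1] s at row {_first_bad_row(bad_rt)} "
            "(exceeds the 1-s trial window)"
        )
    orphan = has_rt & ~df["responded"].to_numpy()
    if orphan.any():
        raise ParseError(
            f"{path}: rt present on an unanswered trial at row {_first_bad_row(orphan)}"
        )
    return df


def read_ratings(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, RATING_COLUMNS, path)
    for col in ("fatigue", "motivation"):
        vals = df[col].to_numpy(dtype=float)
        bad = ~np.isnan(vals) & ((vals < 0) | (vals > 100))
        if bad.any():
            raise ParseError(
                f"{path}: {col} outside [0, 100] at row {_first_bad_row(bad)}"
            )
    dup = df.duplicated(subset=["participant_id", "block_index"])
    if dup.any():
        raise ParseError(f"{path}: duplicate rating key at row {_first_bad_row(dup.to_numpy())}")
    return df


def read_memory(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, MEMORY_COLUMNS, path)
    bad_task = ~df["task"].isin(["object", "word"])
    if bad_task.any():
        raise ParseError(f"{path}: unknown task at row {_first_bad_row(bad_task.to_numpy())}")
    bad_phase = ~df["phase"].isin(["immediate", "delayed"])
    if bad_phase.any():
        raise ParseError(f"{path}: unknown phase at row {_first_bad_row(bad_phase.to_numpy())}")
    bad_outcome = ~df["outcome"].isin(MEMORY_OUTCOME_VALUES)
    if bad_outcome.any():
        raise ParseError(
            f"{path}: unknown outcome at row {_first_bad_row(bad_outcome.to_numpy())}"
        )
    dup = df.duplicated(subset=["participant_id", "task", "phase", "item_index"])
    if dup.any():
        raise ParseError(f"{path}: duplicate probe key at row {_first_bad_row(dup.to_numpy())}")
    return df


def read_participants(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, PARTICIPANT_COLUMNS, path)
    dup = df.duplicated(subset=["participant_id"])
    if dup.any():
        raise ParseError(
            f"{path}: duplicate participant_id at row {_first_bad_row(dup.to_numpy())}"
        )
    return df


def write_tables(
    out_dir,
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    ratings: Optional[pd.DataFrame] = None,
    memory: Optional[pd.DataFrame] = None,
) -> dict:
    """Write cohort tables as CSV into ``out_dir``; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("participants", participants),
        ("trials", trials),
        ("ratings", ratings),
        ("memory", memory),
    ):
        if df is None:
            continue
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def read_tables(data_dir) -> dict:
    """Read every cohort table present in ``data_dir`` (participants and
    trials required, ratings/memory optional)."""
    data_dir = Path(data_dir)
    out = {
        "participants": read_participants(data_dir / "participants.csv"),
        "trials": read_trials(data_dir / "trials.csv"),
    }
    ratings_path = data_dir / "ratings.csv"
    memory_path = data_dir / "memory.csv"
    out["ratings"] = read_ratings(ratings_path) if ratings_path.exists() else None
    out["memory"] = read_memory(memory_path) if memory_path.exists() else None
    return out
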