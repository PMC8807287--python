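"""Memory-probe scoring: immediate/delayed accuracy, the normalized memory
decrement, and the orientation-misbinding false-alarm decomposition.

The object task is an 8-alternative forced choice over 20 items; each probe
outcome is one of ``correct``, ``same_object_wrong_orientation`` (the right
object chosen in the wrong orientation — a binding failure) or
``other_error``.  The memory decrement is delayed minus immediate accuracy,
normalized by immediate accuracy and expressed in percent, mirroring the
vigilance decrement.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .vigilance import InputIntegrityError

__all__ = [
    "score_memory_phase",
    "memory_decrement",
    "group_raw_change_difference",
    "word_memory_accuracy",
    "participant_memory_summary",
    "residualize_on_interval",
]


def score_memory_phase(records: pd.DataFrame) -> Tuple[float, float, float]:
    """Score one participant's object-memory phase.

    Returns ``(accuracy, orientation_fa_rate, mean_rt)`` as unit fractions /
    seconds: accuracy = correct/total, orientation false-alarm rate =
    same_object_wrong_orientation/total.  Raises on an empty record set.
    """
    n = len(records)
    if n == 0:
        raise InputIntegrityError("no memory probe records for this phase")
    outcome = records["outcome"]
    accuracy = float((outcome == "correct").sum()) / n
    orientation_fa = float((outcome == "same_object_wrong_orientation").sum()) / n
    rts = records["rt"].to_numpy(dtype=float) if "rt" in records else np.array([])
    mean_rt = float(np.nanmean(rts)) if rts.size else math.nan
    return accuracy, orientation_fa, mean_rt


def memory_decrement(immediate_accuracy: float, delayed_accuracy: float) -> Tuple[float, float]:
    """Raw and normalized memory decrement.

    ``raw_change`` = delayed - immediate, in the units of the inputs
    (points if percentages were passed);
    ``normalized`` = 100 * raw_change / immediate, which is invariant to
    whether the accuracies arrive as fractions or percentages.  Normalized
    value is NaN when immediate accuracy is zero.
    """
    raw_change = delayed_accuracy - immediate_accuracy
    if immediate_accuracy == 0:
        return raw_change, math.nan
    return raw_change, 100.0 * raw_change / immediate_accuracy


def group_raw_change_difference(
    immediate_a: float, delayed_a: float, immediate_b: float, delayed_b: float
) -> float:
    """Difference of the two groups' raw accuracy changes, in points:
    (delayed_b - immediate_b) - (delayed_a - immediate_a)."""
    return (delayed_b - immediate_b) - (delayed_a - immediate_a)


def word_memory_accuracy(records: pd.DataFrame, n_probes: Optional[int] = None) -> float:
    """Word-recognition accuracy = (hits + correct rejections) / n_probes.

    ``n_probes`` defaults to the number of records (24 in the standard probe
    set, half of them non-targets).
    """
    n = len(records) if n_probes is None else n_probes
    if n == 0:
        raise InputIntegrityError("no word memory records")
    good = records["outcome"].isin(["hit", "correct_rejection"]).sum()
    return float(good) / n


def participant_memory_summary(
    memory: pd.DataFrame, participants: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-participant memory endpoints, in percent.

    One row per participant: immediate/delayed object accuracy, raw change,
    normalized memory decrement, orientation false-alarm rates per phase,
    word accuracies and word decrement when word records exist, and the
    maintenance interval when a participant table is supplied.  Participants
    missing a phase are omitted (listwise).
    """
    obj = memory[memory["task"] == "object"]
    words = memory[memory["task"] == "word"]
    if len(obj) == 0:
        return pd.DataFrame(
            columns=["participant_id", "immediate_accuracy", "delayed_accuracy"]
        )
    # vectorized equivalent of score_memory_phase per (participant, phase)
    grp = obj.groupby(["participant_id", "phase"], sort=True)
    agg = grp.agg(
        n=("outcome", "size"),
        n_correct=("outcome", lambda s: (s == "correct").sum()),
        n_misbind=("outcome", lambda s: (s == "same_object_wrong_orientation").sum()),
        mean_rt=("rt", "mean"),
    )
    agg["accuracy"] = agg["n_correct"] / agg["n"]
    agg["orientation_fa"] = agg["n_misbind"] / agg["n"]
    wide = agg[["accuracy", "orientation_fa", "mean_rt"]].unstack("phase")
    if ("accuracy", "immediate") not in wide.columns or (
        "accuracy",
        "delayed",
    ) not in wide.columns:
        return pd.DataFrame(
            columns=["participant_id", "immediate_accuracy", "delayed_accuracy"]
        )
    complete = wide.dropna(subset=[("accuracy", "immediate"), ("accuracy", "delayed")])
    acc_i = complete[("accuracy", "immediate")].to_numpy()
    acc_d = complete[("accuracy", "delayed")].to_numpy()
    raw = 100.0 * (acc_d - acc_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(acc_i > 0, 100.0 * (acc_d - acc_i) / acc_i, np.nan)
    out = pd.DataFrame(
        {
            "participant_id": complete.index,
            "immediate_accuracy": 100.0 * acc_i,
            "delayed_accuracy": 100.0 * acc_d,
            "raw_change": raw,
            "memory_decrement": norm,
            "orientation_fa_immediate": 100.0 * complete[("orientation_fa", "immediate")].to_numpy(),
            "orientation_fa_delayed": 100.0 * complete[("orientation_fa", "delayed")].to_numpy(),
            "immediate_rt": complete[("mean_rt", "immediate")].to_numpy(),
            "delayed_rt": complete[("mean_rt", "delayed")].to_numpy(),
        }
    )
    if len(words):
        wgrp = words.groupby(["participant_id", "phase"], sort=True)
        wagg = wgrp.agg(
            n=("outcome", "size"),
            n_good=("outcome", lambda s: s.isin(["hit", "correct_rejection"]).sum()),
        )
        wacc = (wagg["n_good"] / wagg["n"]).unstack("phase")
        if "immediate" in wacc.columns and "delayed" in wacc.columns:
            wacc = wacc.dropna()
            wi = wacc["immediate"].to_numpy()
            wd = wacc["delayed"].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                wnorm = np.where(wi > 0, 100.0 * (wd - wi) / wi, np.nan)
            wdf = pd.DataFrame(
                {
                    "participant_id": wacc.index,
                    "word_immediate_accuracy": 100.0 * wi,
                    "word_delayed_accuracy": 100.0 * wd,
                    "word_memory_decrement": wnorm,
                }
            )
            out = out.merge(wdf, on="participant_id", how="left")
    if participants is not None and len(out):
        out = out.merge(
            participants[["participant_id", "maintenance_interval"]],
            on="participant_id",
            how="left",
        )
    return out


def residualize_on_interval(
    decrement: np.ndarray, interval: np.ndarray
) -> np.ndarray:
    """Remove the linear effect of maintenance interval from a decrement
    vector by least squares, returning residuals recentred on the original
    mean.  Used as a robustness check when groups differ in how long memory
    had to be maintained."""
    dec = np.asarray(decrement, dtype=float)
    x = np.asarray(interval, dtype=float)
    ok = ~(np.isnan(dec) | np.isnan(x))
    out = np.full_like(dec, np.nan)
    if ok.sum() < 3:
        return dec.copy()
    X = np.column_stack([np.ones(ok.sum()), x[ok]])
    beta, *_ = np.linalg.lstsq(X, dec[ok], rcond=None)
    out[ok] = dec[ok] - X @ beta + dec[ok].mean()
    return out
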