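"""Vigilance-task scoring: per-block F1 and trimmed RT, per-participant
decrement statistics.

Accuracy in a rare-target detection block is the F1 score

    F1 = 2*TP / (2*TP + FP + FN),

the harmonic mean of precision and sensitivity; correct rejections (TN) are
ignored, which suits a task where 75% of trials require no response.  A
participant's *vigilance decrement* is the change in mean F1 from the first
three main blocks (baseline) to the last three, normalized by the baseline
and expressed in percent:

    decrement = 100 * (final - baseline) / baseline.

The practice block (index 0) is scored — it is the t = 0 point on trajectory
plots — but never enters baseline/final summaries.  Accuracies are carried as
unit fractions internally and converted to percent only in the participant
summary.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "classify_trials",
    "block_f1",
    "block_rt",
    "score_blocks",
    "participant_vigilance_summary",
    "f1_timeseries",
    "InputIntegrityError",
]

BASELINE_BLOCKS = (1, 2, 3)
FINAL_BLOCKS = (7, 8, 9)


class InputIntegrityError(ValueError):
    """Raised when trial records violate structural requirements."""


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Label every trial TP / FP / FN / TN.

    A response during a target trial's one-second window is a true positive;
    a response to a non-target is a false positive; unanswered targets and
    non-targets are false negatives and true negatives respectively.

    Returns a copy with an ``outcome`` column added.  Raises
    :class:`InputIntegrityError` on duplicate (participant, block, trial)
    keys.
    """
    key_cols = ["participant_id", "block_index", "trial_index"]
    if trials.duplicated(subset=key_cols).any():
        dup = trials[trials.duplicated(subset=key_cols, keep=False)].iloc[0]
        raise InputIntegrityError(
            "duplicate trial key "
            f"({dup['participant_id']}, block {dup['block_index']}, trial {dup['trial_index']})"
        )
    out = trials.copy()
    is_target = out["is_target"].to_numpy(dtype=bool)
    responded = out["responded"].to_numpy(dtype=bool)
    outcome = np.where(
        is_target,
        np.where(responded, "TP", "FN"),
        np.where(responded, "FP", "TN"),
    )
    out["outcome"] = outcome
    return out


def block_f1(tp: int, fp: int, fn: int) -> float:
    """F1 = 2*TP / (2*TP + FP + FN); NaN when the denominator is zero
    (a block with no targets and no false alarms carries no signal)."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError(f"outcome counts must be non-negative, got tp={tp}, fp={fp}, fn={fn}")
    denom = 2 * tp + fp + fn
    if denom == 0:
        return math.nan
    return 2.0 * tp / denom


def block_rt(rts: Sequence[float]) -> Tuple[float, int]:
    """Mean correct-response RT for one block after one-pass 2-SD trimming.

    Only true-positive RTs should be passed in.  Values farther than two
    sample standard deviations (ddof=1) from the block mean are excluded,
    once (not iterated).  With fewer than three RTs the spread estimate is
    meaningless, so trimming is skipped.  Returns ``(mean_rt, n_excluded)``;
    ``(nan, 0)`` for an empty block.
    """
    arr = np.asarray([r for r in rts if not (r is None or np.isnan(r))], dtype=float)
    if arr.size == 0:
        return math.nan, 0
    if arr.size < 3:
        return float(arr.mean()), 0
    mu, sd = arr.mean(), arr.std(ddof=1)
    keep = np.abs(arr - mu) <= 2.0 * sd
    if not keep.any():  # pathological: all points beyond 2 SD cannot happen, but guard
        return float(mu), 0
    return float(arr[keep].mean()), int((~keep).sum())


def score_blocks(trials: pd.DataFrame) -> pd.DataFrame:
    """Score every (participant, block): outcome counts, F1, trimmed mean RT.

    Vectorized equivalent of applying :func:`block_f1` and :func:`block_rt`
    block by block (the per-block functions remain the reference semantics).
    Returns one row per participant x block with columns
    ``participant_id, block_index, tp, fp, fn, tn, f1, mean_rt, n_rt_excluded``.
    """
    labelled = classify_trials(trials)
    keys = ["participant_id", "block_index"]
    counts = (
        labelled.pivot_table(
            index=keys, columns="outcome", values="trial_index", aggfunc="size", fill_value=0
        )
        .reindex(columns=["TP", "FP", "FN", "TN"], fill_value=0)
        .reset_index()
        .rename(columns={"TP": "tp", "FP": "fp", "FN": "fn", "TN": "tn"})
    )
    counts.columns.name = None
    denom = 2 * counts["tp"] + counts["fp"] + counts["fn"]
    counts["f1"] = np.where(denom > 0, 2.0 * counts["tp"] / denom.replace(0, 1), np.nan)

    # trimmed RT over true-positive trials: one-pass 2-SD exclusion within the
    # block, skipped when fewer than 3 RTs are available
    tp_rts = labelled[(labelled["outcome"] == "TP") & labelled["rt"].notna()][keys + ["rt"]]
    if len(tp_rts):
        g = tp_rts.groupby(keys)["rt"]
        mu = g.transform("mean")
        sd = g.transform("std")  # ddof=1
        n = g.transform("size")
        keep = (n < 3) | ((tp_rts["rt"] - mu).abs() <= 2.0 * sd)
        kept_mean = tp_rts[keep].groupby(keys)["rt"].mean().rename("mean_rt")
        n_excl = (
            (~keep).groupby([tp_rts[k] for k in keys]).sum().rename("n_rt_excluded")
        )
        rt_summary = pd.concat([kept_mean, n_excl], axis=1).reset_index()
        counts = counts.merge(rt_summary, on=keys, how="left")
        counts["n_rt_excluded"] = counts["n_rt_excluded"].fillna(0).astype(int)
    else:
        counts["mean_rt"] = np.nan
        counts["n_rt_excluded"] = 0
    return counts.sort_values(keys, ignore_index=True)


def _phase_mean(pivot: pd.DataFrame, blocks: Iterable[int]) -> pd.Series:
    cols = [b for b in blocks if b in pivot.columns]
    if len(cols) < len(list(blocks)):
        return pd.Series(math.nan, index=pivot.index)
    return pivot[cols].mean(axis=1, skipna=False)


def participant_vigilance_summary(
    block_scores: pd.DataFrame,
    ratings: Optional[pd.DataFrame] = None,
    n_blocks: int = 9,
) -> pd.DataFrame:
    """Per-participant vigilance endpoints, in percent.

    baseline_accuracy   mean F1 over blocks 1-3, %
    final_accuracy      mean F1 over blocks 7-9, %
    absolute_change     final - baseline, percentage points
    vigilance_decrement 100 * absolute_change / baseline_accuracy, %
    overall_accuracy    mean F1 over blocks 1-9, %
    rt_change_normalized 100 * (final RT - baseline RT) / baseline RT, %
    fatigue/motivation  baseline = mean rating after blocks 1-3;
                        change = mean(after 7-9) - mean(after 1-3)

    A participant whose baseline is 0 (or whose baseline/final blocks carry
    undefined F1) gets NaN decrement and ``decrement_defined = False``;
    downstream normalized-decrement comparisons drop such rows listwise.
    """
    f1 = block_scores.pivot(index="participant_id", columns="block_index", values="f1")
    baseline = _phase_mean(f1, BASELINE_BLOCKS)
    final = _phase_mean(f1, FINAL_BLOCKS)
    overall = _phase_mean(f1, range(1, n_blocks + 1))
    abs_change = final - baseline
    defined = baseline.notna() & (baseline > 0) & final.notna()
    decrement = pd.Series(math.nan, index=f1.index)
    decrement[defined] = 100.0 * abs_change[defined] / baseline[defined]
    rt = block_scores.pivot(index="participant_id", columns="block_index", values="mean_rt")
    rt_base = _phase_mean(rt, BASELINE_BLOCKS)
    rt_final = _phase_mean(rt, FINAL_BLOCKS)
    rt_ok = rt_base.notna() & (rt_base > 0) & rt_final.notna()
    rt_change = pd.Series(math.nan, index=f1.index)
    rt_change[rt_ok] = 100.0 * (rt_final[rt_ok] - rt_base[rt_ok]) / rt_base[rt_ok]
    out = pd.DataFrame(
        {
            "participant_id": f1.index,
            "baseline_accuracy": 100.0 * baseline.to_numpy(),
            "final_accuracy": 100.0 * final.to_numpy(),
            "absolute_change": 100.0 * abs_change.to_numpy(),
            "vigilance_decrement": decrement.to_numpy(),
            "decrement_defined": defined.to_numpy(),
            "overall_accuracy": 100.0 * overall.to_numpy(),
            "rt_change_normalized": rt_change.to_numpy(),
        }
    )
    if ratings is not None:
        for col in ("fatigue", "motivation"):
            piv = ratings.pivot(index="participant_id", columns="block_index", values=col)
            piv = piv.reindex(f1.index)
            base = _phase_mean(piv, BASELINE_BLOCKS)
            last = _phase_mean(piv, FINAL_BLOCKS)
            out[f"{col}_baseline"] = base.to_numpy()
            out[f"{col}_change"] = (last - base).to_numpy()
    return out.reset_index(drop=True)


def f1_timeseries(
    block_scores: pd.DataFrame, include_practice: bool = True
) -> pd.DataFrame:
    """Wide participants x blocks matrix of F1 (unit fractions) for the
    time-series bootstrap; practice block 0 included by default as t = 0."""
    sub = block_scores if include_practice else block_scores[block_scores["block_index"] > 0]
    return sub.pivot(index="participant_id", columns="block_index", values="f1")
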