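"""Synthetic two-group cognitive cohort generator.

Emulates the data-generating structure of an online sustained-attention +
episodic-memory study: each participant completes a practice minute plus nine
one-minute detection blocks (60 one-second trials, 25% targets), rates fatigue
and motivation after every minute, and answers 20-item 8-alternative
object-memory probes immediately after encoding and again ~30 min later,
together with a 24-word recognition probe.  The exposed group carries a
steeper per-minute decline in hit probability and an inflated probability of
same-object/wrong-orientation errors at the delayed memory test; both effects
shrink linearly with time since diagnosis and vanish beyond a recovery
horizon.

Every participant owns an independent RNG stream derived from
``(seed, participant_id)``, so enlarging a cohort never perturbs previously
generated participants.
"""

from __future__ import annotations

import zlib
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .config import CohortConfig, ConfigurationError, GroupParams

__all__ = [
    "generate_cohort",
    "generate_memory_session",
    "participant_rng",
    "expected_group_decrement",
]

HIT_PROB_CLIP = (0.01, 0.99)

# female fraction and questionnaire scale (mean, sd) per group, used only to
# furnish realistic covariate columns
_P_FEMALE = {"a": 0.434, "b": 0.373}
_SCALE_SCORES = {
    "a": {
        "grit": (3.1, 0.6),
        "nfi_physical_fatigue": (8.4, 4.4),
        "cfq_forgetfulness": (13.0, 4.8),
        "ami_behavioural": (10.9, 4.5),
        "hads_depression": (5.4, 3.9),
        "hads_anxiety": (8.0, 4.0),
    },
    "b": {
        "grit": (3.3, 0.8),
        "nfi_physical_fatigue": (9.2, 4.9),
        "cfq_forgetfulness": (12.4, 5.2),
        "ami_behavioural": (9.8, 4.2),
        "hads_depression": (5.4, 3.3),
        "hads_anxiety": (8.3, 3.7),
    },
}

MEMORY_OUTCOMES = ("correct", "same_object_wrong_orientation", "other_error")
WORD_OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection")


def participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one participant."""
    tag = zlib.crc32(participant_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def _truncated_lognormal(
    rng: np.random.Generator, log_mean: float, log_sd: float, size: int, upper: float = 1.0
) -> np.ndarray:
    """Log-normal draws truncated to (0, upper] via inverse-CDF sampling."""
    if log_sd == 0.0:
        return np.full(size, min(np.exp(log_mean), upper))
    z_hi = (np.log(upper) - log_mean) / log_sd
    u = ndtr(z_hi) * rng.random(size)
    u = np.clip(u, 1e-12, None)
    return np.exp(log_mean + log_sd * ndtri(u))


def _recovery_factor(days: float, tau: float) -> float:
    return max(0.0, 1.0 - days / tau)


def _memory_session_arrays(
    p_correct: float,
    p_misbind: float,
    phase: str,
    delay_misbind_inflation: float,
    n_items: int,
    rng: np.random.Generator,
    rt_log_mean: Optional[float],
    rt_log_sd: float,
) -> Tuple[np.ndarray, np.ndarray]:
    if phase not in {"immediate", "delayed"}:
        raise ValueError(f"phase must be 'immediate' or 'delayed', got {phase!r}")
    pc, pm = float(p_correct), float(p_misbind)
    if phase == "delayed":
        pc -= delay_misbind_inflation
        pm += delay_misbind_inflation
    po = 1.0 - pc - pm
    probs = np.array([pc, pm, po])
    if np.any(probs < -1e-12) or np.any(probs > 1.0 + 1e-12):
        raise ConfigurationError(
            "memory category probabilities out of [0, 1] after delay inflation: "
            f"correct={pc:.4f}, misbind={pm:.4f}, other={po:.4f}"
        )
    probs = np.clip(probs, 0.0, 1.0)
    probs = probs / probs.sum()
    idx = rng.choice(3, size=n_items, p=probs)
    if rt_log_mean is None:
        rt_log_mean = np.log(3.2) if phase == "immediate" else np.log(2.3)
    rts = np.round(np.exp(rng.normal(rt_log_mean, rt_log_sd, size=n_items)), 4)
    return np.asarray(MEMORY_OUTCOMES)[idx], rts


def generate_memory_session(
    p_correct: float,
    p_misbind: float,
    phase: str,
    delay_misbind_inflation: float = 0.0,
    n_items: int = 20,
    rng: Optional[np.random.Generator] = None,
    rt_log_mean: Optional[float] = None,
    rt_log_sd: float = 0.4,
) -> pd.DataFrame:
    """Simulate one object-memory probe phase for one participant.

    At ``phase == "delayed"`` the inflation mass is moved from ``correct`` to
    ``same_object_wrong_orientation``; the ``other_error`` mass is unchanged.
    Returns one record per item with columns ``item_index, outcome, rt``.
    """
    if rng is None:
        rng = np.random.default_rng()
    outcome, rts = _memory_session_arrays(
        p_correct, p_misbind, phase, delay_misbind_inflation, n_items, rng,
        rt_log_mean, rt_log_sd,
    )
    return pd.DataFrame(
        {"item_index": np.arange(n_items), "outcome": outcome, "rt": rts}
    )


def _word_session_arrays(
    p_correct: float, n_probes: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """24-word recognition probe: half targets, half non-targets; each probe is
    answered correctly with probability ``p_correct``."""
    n_targets = n_probes // 2
    is_target = np.zeros(n_probes, dtype=bool)
    is_target[:n_targets] = True
    correct = rng.random(n_probes) < p_correct
    outcome = np.where(
        is_target,
        np.where(correct, "hit", "miss"),
        np.where(correct, "correct_rejection", "false_alarm"),
    )
    rts = np.round(np.exp(rng.normal(np.log(1.0), 0.3, size=n_probes)), 4)
    return outcome, rts


def _simulate_participant(
    pid: str,
    group_key: str,
    group_name: str,
    params: GroupParams,
    config: CohortConfig,
) -> Tuple[dict, dict, dict, dict]:
    rng = participant_rng(config.seed, pid)

    # --- metadata and covariates -------------------------------------------
    age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 18.0, 75.0))
    gender = "female" if rng.random() < _P_FEMALE[group_key] else "male"
    if group_key == "a":
        lo, hi = config.days_since_diagnosis_range
        days = float(np.round(rng.uniform(lo, hi), 1))
        recov_vig = _recovery_factor(days, config.recovery_tau_days)
        recov_mem = _recovery_factor(days, config.memory_recovery_tau_days)
    else:
        days = np.nan
        recov_vig = recov_mem = 1.0
    latent = rng.normal()
    maintenance = float(
        np.round(max(5.0, rng.normal(params.maintenance_mean_min, params.maintenance_sd_min)), 1)
    )
    meta = {
        "participant_id": pid,
        "group": group_name,
        "age": round(age, 1),
        "gender": gender,
        "days_since_diagnosis": days,
        "maintenance_interval": maintenance,
    }
    for name, (mu, sd) in _SCALE_SCORES[group_key].items():
        meta[name] = round(float(rng.normal(mu, sd)), 2)

    # --- vigilance trials ---------------------------------------------------
    n_blocks_total = config.n_blocks + 1  # practice block 0
    tpb = config.trials_per_block
    n_trials = n_blocks_total * tpb
    block_index = np.repeat(np.arange(n_blocks_total), tpb)
    trial_index = np.tile(np.arange(tpb), n_blocks_total)

    h0 = float(
        np.clip(
            rng.normal(params.baseline_hit_rate_mean, params.baseline_hit_rate_sd),
            *HIT_PROB_CLIP,
        )
    )
    drift_eff = (
        params.hit_drift_per_block * recov_vig
        + config.shared_latent_vigilance_scale * latent
    )
    hit_prob_by_block = np.clip(h0 + drift_eff * np.arange(n_blocks_total), *HIT_PROB_CLIP)
    hit_prob = hit_prob_by_block[block_index]

    is_target = rng.random(n_trials) < config.target_prob
    stimulus = np.where(is_target, 0, rng.integers(1, 10, size=n_trials))
    responded = np.where(
        is_target, rng.random(n_trials) < hit_prob, rng.random(n_trials) < config.fa_rate
    )
    rt = np.full(n_trials, np.nan)
    n_resp = int(responded.sum())
    rt[responded] = np.round(
        _truncated_lognormal(rng, config.rt_log_mean, config.rt_log_sd, n_resp), 4
    )
    trials = {
        "participant_id": np.repeat(pid, n_trials),
        "block_index": block_index,
        "trial_index": trial_index,
        "stimulus_digit": stimulus,
        "is_target": is_target,
        "responded": responded,
        "rt": rt,
    }

    # --- block ratings (after practice and after each block: 10 ratings) ----
    blocks = np.arange(n_blocks_total)
    fatigue = np.clip(
        params.fatigue_start
        + params.fatigue_slope * blocks
        + rng.normal(0.0, config.rating_noise_sd, n_blocks_total),
        0.0,
        100.0,
    )
    motivation = np.clip(
        params.motivation_start
        + params.motivation_slope * blocks
        + rng.normal(0.0, config.rating_noise_sd, n_blocks_total),
        0.0,
        100.0,
    )
    ratings = {
        "participant_id": np.repeat(pid, n_blocks_total),
        "block_index": blocks,
        "fatigue": np.round(fatigue, 2),
        "motivation": np.round(motivation, 2),
    }

    # --- memory probes ------------------------------------------------------
    infl_eff = params.delay_misbind_inflation * recov_mem + (
        config.shared_latent_memory_scale * latent
    )
    # keep the delayed category simplex valid under latent perturbation
    infl_eff = float(
        np.clip(
            infl_eff,
            -params.memory_p_misbind_immediate,
            params.memory_p_correct_immediate,
        )
    )
    tasks, phases, items, outcomes, rts = [], [], [], [], []
    for phase in ("immediate", "delayed"):
        outcome, rt_arr = _memory_session_arrays(
            params.memory_p_correct_immediate,
            params.memory_p_misbind_immediate,
            phase,
            infl_eff,
            config.memory_n_items,
            rng,
            None,
            0.4,
        )
        tasks.append(np.repeat("object", config.memory_n_items))
        phases.append(np.repeat(phase, config.memory_n_items))
        items.append(np.arange(config.memory_n_items))
        outcomes.append(outcome)
        rts.append(rt_arr)
    for phase, p in (
        ("immediate", params.word_p_correct_immediate),
        ("delayed", params.word_p_correct_delayed),
    ):
        outcome, rt_arr = _word_session_arrays(p, config.word_n_probes, rng)
        tasks.append(np.repeat("word", config.word_n_probes))
        phases.append(np.repeat(phase, config.word_n_probes))
        items.append(np.arange(config.word_n_probes))
        outcomes.append(outcome)
        rts.append(rt_arr)
    n_mem = sum(len(t) for t in tasks)
    memory = {
        "participant_id": np.repeat(pid, n_mem),
        "task": np.concatenate(tasks),
        "phase": np.concatenate(phases),
        "item_index": np.concatenate(items),
        "outcome": np.concatenate(outcomes),
        "rt": np.concatenate(rts),
    }

    return meta, trials, ratings, memory


def generate_cohort(
    config: CohortConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns
    -------
    (participants, trials, ratings, memory) : tuple of DataFrame
        Participant metadata, vigilance trials, per-block ratings, and memory
        probe records, with the fixed column layouts documented in
        :mod:`vigimem.io`.  Deterministic given ``config.seed``.
    """
    metas, trial_frames, rating_frames, memory_frames = [], [], [], []
    groups = [
        ("a", config.group_a_name, config.n_group_a, config.group_a),
        ("b", config.group_b_name, config.n_group_b, config.group_b),
    ]
    for key, name, n, params in groups:
        for i in range(n):
            pid = f"{name}_{i:03d}"
            meta, trials, ratings, memory = _simulate_participant(
                pid, key, name, params, config
            )
            metas.append(meta)
            trial_frames.append(trials)
            rating_frames.append(ratings)
            memory_frames.append(memory)
    participants = pd.DataFrame(metas)

    def _concat(parts: list) -> pd.DataFrame:
        return pd.DataFrame(
            {k: np.concatenate([p[k] for p in parts]) for k in parts[0]}
        )

    return (
        participants,
        _concat(trial_frames),
        _concat(rating_frames),
        _concat(memory_frames),
    )


def _expected_f1(hit_prob: np.ndarray, target_prob: float, fa_rate: float) -> np.ndarray:
    """Expected-count F1 for a block with per-trial hit probability ``hit_prob``.

    Uses expected TP/FP/FN per trial: TP = p_t*h, FN = p_t*(1-h),
    FP = (1-p_t)*fa.  The trials-per-block factor cancels.
    """
    tp = target_prob * hit_prob
    fn = target_prob * (1.0 - hit_prob)
    fp = (1.0 - target_prob) * fa_rate
    return 2.0 * tp / (2.0 * tp + fp + fn)


def expected_group_decrement(
    config: CohortConfig, group: str = "a", n_grid: int = 2001
) -> float:
    """Deterministic expectation of the normalized vigilance decrement (in %)
    for one group under the linear hit-drift model, averaging over the
    baseline-hit-rate distribution and (for the exposed group) the uniform
    days-since-diagnosis distribution.

    This ignores trial-level binomial noise: each participant's block F1 is
    replaced by its expected-count value, so the result is the infinite-trial
    limit of the scored group mean decrement.
    """
    params = config.group_params(group)
    # baseline hit-rate grid: equal-probability normal quantiles, clipped
    q = (np.arange(n_grid) + 0.5) / n_grid
    h0 = np.clip(
        params.baseline_hit_rate_mean + params.baseline_hit_rate_sd * ndtri(q),
        *HIT_PROB_CLIP,
    )
    if group == "a":
        lo, hi = config.days_since_diagnosis_range
        days = lo + (hi - lo) * (np.arange(101) + 0.5) / 101
        recov = np.maximum(0.0, 1.0 - days / config.recovery_tau_days)
    else:
        recov = np.array([1.0])
    drift = params.hit_drift_per_block * recov  # shape (R,)
    blocks_base = np.array([1, 2, 3])
    blocks_final = np.array([7, 8, 9])
    # hit prob per (h0, recov, block)
    h_base = np.clip(
        h0[:, None, None] + drift[None, :, None] * blocks_base[None, None, :], *HIT_PROB_CLIP
    )
    h_final = np.clip(
        h0[:, None, None] + drift[None, :, None] * blocks_final[None, None, :], *HIT_PROB_CLIP
    )
    f1_base = _expected_f1(h_base, config.target_prob, config.fa_rate).mean(axis=2)
    f1_final = _expected_f1(h_final, config.target_prob, config.fa_rate).mean(axis=2)
    dec = 100.0 * (f1_final - f1_base) / f1_base
    return float(dec.mean())
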