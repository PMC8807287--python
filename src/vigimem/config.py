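"""Cohort simulation configuration.

The defaults describe a two-group online vigilance + memory study: an exposed
group (post-infection) and an age-matched control group, each completing a
practice minute plus nine 60-trial one-second-cadence detection blocks, ten
fatigue/motivation ratings, and a 20-item 8-alternative object-memory probe
tested immediately and again after roughly half an hour, plus a 24-word
recognition probe.  All probabilities are unit fractions; ratings are on a
0-100 visual-analogue scale; times are seconds unless a field name says
otherwise.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["GroupParams", "CohortConfig", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


class GroupParams(BaseModel):
    """Data-generating parameters for one participant group."""

    model_config = ConfigDict(extra="forbid")

    # vigilance task
    baseline_hit_rate_mean: float = Field(ge=0.0, le=1.0)
    baseline_hit_rate_sd: float = Field(ge=0.0)
    hit_drift_per_block: float = Field(
        description="signed change in per-trial hit probability per block (minute)"
    )
    # block ratings, 0-100 scale
    fatigue_start: float = Field(ge=0.0, le=100.0)
    fatigue_slope: float
    motivation_start: float = Field(ge=0.0, le=100.0)
    motivation_slope: float
    # object memory (8-AFC over 20 items)
    memory_p_correct_immediate: float = Field(ge=0.0, le=1.0)
    memory_p_misbind_immediate: float = Field(
        ge=0.0, le=1.0,
        description="probability of choosing the right object in the wrong orientation",
    )
    delay_misbind_inflation: float = Field(
        description="probability mass moved from correct to wrong-orientation at delay"
    )
    # word recognition (24 probes, half non-targets)
    word_p_correct_immediate: float = Field(default=0.91, ge=0.0, le=1.0)
    word_p_correct_delayed: float = Field(default=0.86, ge=0.0, le=1.0)
    # delay between immediate and delayed memory tests, minutes
    maintenance_mean_min: float = Field(gt=0.0)
    maintenance_sd_min: float = Field(ge=0.0)
    # demographics
    age_mean: float = 28.6
    age_sd: float = 9.7

    @model_validator(mode="after")
    def _check_memory_simplex(self) -> "GroupParams":
        if self.memory_p_correct_immediate + self.memory_p_misbind_immediate > 1.0 + 1e-12:
            raise ConfigurationError(
                "memory_p_correct_immediate + memory_p_misbind_immediate exceeds 1"
            )
        delayed_correct = self.memory_p_correct_immediate - self.delay_misbind_inflation
        delayed_misbind = self.memory_p_misbind_immediate + self.delay_misbind_inflation
        if not (0.0 <= delayed_correct <= 1.0 and 0.0 <= delayed_misbind <= 1.0):
            raise ConfigurationError(
                "delay_misbind_inflation pushes delayed category probabilities out of [0, 1]"
            )
        return self


def _default_group_a() -> GroupParams:
    # exposed group: steeper vigilance drift, delayed misbinding inflation
    return GroupParams(
        baseline_hit_rate_mean=0.764,
        baseline_hit_rate_sd=0.20,
        hit_drift_per_block=-0.053,
        fatigue_start=62.0,
        fatigue_slope=1.2,
        motivation_start=53.0,
        motivation_slope=-2.2,
        memory_p_correct_immediate=0.60,
        memory_p_misbind_immediate=0.30,
        delay_misbind_inflation=0.20,
        word_p_correct_immediate=0.91,
        word_p_correct_delayed=0.86,
        maintenance_mean_min=27.9,
        maintenance_sd_min=8.7,
        age_mean=28.0,
        age_sd=8.6,
    )


def _default_group_b() -> GroupParams:
    return GroupParams(
        baseline_hit_rate_mean=0.779,
        baseline_hit_rate_sd=0.20,
        hit_drift_per_block=-0.0017,
        fatigue_start=50.0,
        fatigue_slope=1.6,
        motivation_start=56.0,
        motivation_slope=-2.3,
        memory_p_correct_immediate=0.60,
        memory_p_misbind_immediate=0.29,
        delay_misbind_inflation=0.0,
        word_p_correct_immediate=0.91,
        word_p_correct_delayed=0.86,
        maintenance_mean_min=29.6,
        maintenance_sd_min=9.9,
        age_mean=29.0,
        age_sd=10.3,
    )


class CohortConfig(BaseModel):
    """Full configuration for :func:`vigimem.synthetic.generate_cohort`.

    The defaults are the study-like conditions: 53 exposed vs 83 control
    participants, nine one-minute blocks plus a practice block, 25% target
    probability, and group decrement parameters that place the normalized
    vigilance decrement near -12% (exposed) vs -1% (control) and inflate
    same-object/wrong-orientation memory errors at delay in the exposed
    group only.
    """

    model_config = ConfigDict(extra="forbid")

    n_group_a: int = Field(default=53, ge=1)
    n_group_b: int = Field(default=83, ge=1)
    group_a_name: str = "covid"
    group_b_name: str = "control"

    n_blocks: int = Field(default=9, ge=1, description="main blocks; a practice block 0 is added")
    trials_per_block: int = Field(default=60, ge=1)
    target_prob: float = Field(default=0.25, ge=0.0, le=1.0)
    fa_rate: float = Field(default=0.05, ge=0.0, le=1.0)

    # reaction times: log-normal truncated to (0, 1 s]
    rt_log_mean: float = -0.80
    rt_log_sd: float = Field(default=0.25, ge=0.0)

    rating_noise_sd: float = Field(default=8.0, ge=0.0)

    memory_n_items: int = Field(default=20, ge=1)
    word_n_probes: int = Field(default=24, ge=2)

    # recovery with time since diagnosis (exposed group only)
    days_since_diagnosis_range: Tuple[float, float] = (10.0, 400.0)
    recovery_tau_days: float = Field(default=270.0, gt=0.0)
    memory_recovery_tau_days: float = Field(default=180.0, gt=0.0)

    # optional shared latent factor coupling the two decrements (unit normal,
    # scaled); 0 disables it
    shared_latent_vigilance_scale: float = 0.0
    shared_latent_memory_scale: float = 0.0

    seed: int = 0

    group_a: GroupParams = Field(default_factory=_default_group_a)
    group_b: GroupParams = Field(default_factory=_default_group_b)

    @model_validator(mode="after")
    def _check_ranges(self) -> "CohortConfig":
        lo, hi = self.days_since_diagnosis_range
        if not (0.0 <= lo <= hi):
            raise ConfigurationError(
                "days_since_diagnosis_range must satisfy 0 <= low <= high"
            )
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortConfig":
        """Load a config from JSON or YAML (by extension)."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml  # lazy; only needed for YAML configs

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)

    def group_params(self, which: str) -> GroupParams:
        if which == "a":
            return self.group_a
        if which == "b":
            return self.group_b
        raise ValueError(f"unknown group key {which!r}")


def validate_config(data: dict) -> CohortConfig:
    """Validate a raw mapping, re-raising pydantic errors as ConfigurationError
    naming the offending field."""
    try:
        return CohortConfig.model_validate(data)
    except ConfigurationError:
        raise
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigurationError(str(exc)) from exc
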