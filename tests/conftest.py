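import numpy as np
import pandas as pd
import pytest

from vigimem.config import CohortConfig
from vigimem.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = CohortConfig(n_group_a=10, n_group_b=12, seed=7)
    participants, trials, ratings, memory = generate_cohort(cfg)
    return {
        "config": cfg,
        "participants": participants,
        "trials": trials,
        "ratings": ratings,
        "memory": memory,
    }


def make_block_scores(pid: str, f1_by_block: dict, mean_rt: float = 0.5) -> pd.DataFrame:
    """Hand-built per-block score table for summary arithmetic tests."""
    rows = []
    for block, f1 in f1_by_block.items():
        rows.append(
            {
                "participant_id": pid,
                "block_index": block,
                "tp": 10,
                "fp": 0,
                "fn": 0,
                "tn": 45,
                "f1": f1,
                "mean_rt": mean_rt,
                "n_rt_excluded": 0,
            }
        )
    return pd.DataFrame(rows)
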