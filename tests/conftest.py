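import numpy as np
import pandas as pd
import pytest

import resst
from resst.agents import ddm_sample

CONDITIONS = ("Gplus", "Neutral", "Splus")


@pytest.fixture(scope="session")
def default_cohort_trials():
    """14-subject test-phase cohort from the shipped default template."""
    params = resst.make_cohort(
        resst.CohortSpec(
            14, resst.DEFAULT_TEMPLATE, resst.DEFAULT_HETEROGENEITY, seed=42
        )
    )
    return resst.simulate_cohort(params, resst.SessionConfig(), seed=42)


@pytest.fixture(scope="session")
def default_cohort_summaries(default_cohort_trials):
    return resst.summarize_cohort(default_cohort_trials)


def make_ddm_trials(params, n_per_cond, seed, subject_id="s01"):
    """Tidy go-trial table sampled from a diffusion agent (no stop trials)."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond in CONDITIONS:
        ch, rt = ddm_sample(params, cond, n_per_cond, rng)
        for c, r in zip(ch, rt):
            if c == 0:
                continue
            rows.append(
                {
                    "subject_id": subject_id,
                    "phase": "test",
                    "condition": cond,
                    "trial_type": "go",
                    "rt_ms": r,
                    "outcome": "correct_go" if c == 1 else "failed_go_wrongkey",
                }
            )
    return pd.DataFrame(rows)
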