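import numpy as np
import pandas as pd
import pytest

from bccstrat import GeneratorConfig, generate_cohort
from bccstrat.simulate import bcc_columns


@pytest.fixture(scope="session")
def default_cohort():
    """Default study-size cohort (143 F / 190 M, 71 BCCs) with planted truth."""
    cfg = GeneratorConfig(seed=7)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def small_planted():
    """Small, fast cohort with strong signal in three shared clusters."""
    cfg = GeneratorConfig(
        seed=13,
        n_female=60,
        n_male=60,
        n_bcc=16,
        n_clusters=12,
        sex_shift_vars={},
        informative_clusters={"shared": {0: 1.2, 4: 1.2, 8: -1.2}},
        etiology_clusters={"shared": {0: (1.2, -1.2)}},
    )
    cohort, truth = generate_cohort(cfg)
    partition = {v: c + 1 for v, c in truth.cluster_assignment.items()}
    return cfg, cohort, truth, partition


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def intake_frame():
    """Hand-built eligibility intake table covering every exclusion reason."""
    base = "2019-03-01 "
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(6)],
            "evt_performed": [1, 1, 1, 1, 0, 1],
            "arrival_time": [base + "10:00"] * 6,
            "bcc_time": [
                base + "10:59",  # inside window, before EVT -> keep
                base + "11:00",  # exactly 60 min -> keep (inclusive)
                base + "11:01",  # 61 min -> no_bcc_60min
                base + "12:30",  # after EVT start -> post_evt_sample
                base + "10:30",  # EVT not performed
                "not a time",    # bad_timestamp
            ],
            "evt_start_time": [base + "12:00"] * 6,
        }
    )


def bcc_cols(cfg):
    return bcc_columns(cfg.n_bcc)
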