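import numpy as np
import pandas as pd
import pytest

from bilatdr.cohort import Cohort
from bilatdr.simulate import SimulationConfig, simulate_cohort


def make_cohort_df(n=3, **overrides):
    """Small well-formed cohort table for ingest/filter tests."""
    base = {
        "patient_id": [f"P{i:03d}" for i in range(n)],
        "age_pbc": [55.0 + i for i in range(n)],
        "age_cbc": [60.0 + i for i in range(n)],
        "interval_time": [5.0] * n,
        "race": ["white"] * n,
        "marital_pair": ["WithP/WithP"] * n,
        "t_pbc": ["T1"] * n,
        "t_cbc": ["T2"] * n,
        "n_pbc": ["N0"] * n,
        "n_cbc": ["N1"] * n,
        "grade_pbc": ["I-II"] * n,
        "grade_cbc": ["III-IV"] * n,
        "er_pbc": ["+"] * n,
        "er_cbc": ["-"] * n,
        "pathology_pbc": ["IDC"] * n,
        "pathology_cbc": ["ILC"] * n,
        "surgery_pbc": ["BCM"] * n,
        "surgery_cbc": ["SM"] * n,
        "followup_time": [2.0] * n,
        "event": [1] * n,
        "distant_met": [False] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def tiny_df():
    return make_cohort_df(3)


@pytest.fixture(scope="session")
def sim_cohort():
    """Medium simulated cohort shared across model-level tests."""
    cfg = SimulationConfig(n=6000, seed=123)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def big_sim_cohort():
    """Large cohort for the end-to-end weight-recovery acceptance test."""
    cfg = SimulationConfig(n=50000, seed=42)
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


def as_cohort(df, provenance="test"):
    return Cohort(df, provenance=provenance)
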