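import numpy as np
import pandas as pd
import pytest

from vaprot.simulate import (
    SimConfig,
    simulate_four_vessel,
    simulate_longitudinal,
    clock_cohort_config,
)


@pytest.fixture(scope="session")
def small_four_vessel():
    """A modest planted four-vessel cohort shared by read-only tests."""
    cfg = SimConfig(n_participants=40, n_proteins=300, frac_released=0.05,
                    frac_uptake=0.02, frac_arm_exchange=0.10,
                    release_effect=1.0, uptake_effect=-1.0, arm_effect=1.0, seed=42)
    table, truth = simulate_four_vessel(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def clock_cohort():
    """Longitudinal cohort with 5 planted clock proteins among 200."""
    cfg = clock_cohort_config(seed=3)
    table, truth = simulate_longitudinal(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_longitudinal_frame(values_by_participant, ga_by_participant, protein="seq_x"):
    """Hand-built long-format longitudinal table for unit fixtures."""
    rows = []
    for pid, (vals, gas) in enumerate(zip(values_by_participant, ga_by_participant)):
        for visit, (v, g) in enumerate(zip(vals, gas), start=1):
            rows.append({"participant_id": f"P{pid:03d}", "visit": visit,
                         "ga_weeks": g, "age_years": 30.0, "bmi": 24.0,
                         "nulliparity": 0, protein: v})
    return pd.DataFrame(rows)
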