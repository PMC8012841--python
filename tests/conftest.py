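import numpy as np
import pandas as pd
import pytest

from alsresponder import cohorts


@pytest.fixture(scope="session")
def small_control():
    spec = cohorts.default_control_spec(400, seed=11)
    return cohorts.generate_control_cohort(spec)


@pytest.fixture(scope="session")
def small_treated():
    spec = cohorts.default_treated_spec(36, seed=12)
    table, flags = cohorts.generate_treated_cohort(spec)
    return table, flags


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def two_arm_exponential(n_per_arm, hr, scale_control=300.0, seed=0,
                        censor=np.inf):
    """Simulated two-arm PH data with a known hazard ratio (test oracle input)."""
    r = np.random.default_rng(seed)
    t0 = r.exponential(scale_control, n_per_arm)
    t1 = r.exponential(scale_control / hr, n_per_arm)
    t = np.concatenate([t0, t1])
    d = (t <= censor).astype(int)
    t = np.minimum(t, censor)
    return pd.DataFrame({
        "survival_days": t, "event": d,
        "arm": np.repeat([0, 1], n_per_arm),
    })
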