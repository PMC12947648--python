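import numpy as np
import pandas as pd
import pytest

from spanlife.pipeline import disease_free_outcome
from spanlife.prep import assign_tertiles, make_joint_categories, winsorise
from spanlife.rates import synthetic_disease_rates, synthetic_mortality_rates
from spanlife.synthgen import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def national_rates():
    return synthetic_mortality_rates()


@pytest.fixture(scope="session")
def disease_rates():
    return synthetic_disease_rates()


@pytest.fixture(scope="session")
def cohort8k() -> pd.DataFrame:
    """One mid-sized cohort with the default effect structure, shared by the
    model-fitting tests (generation is cheap, Cox fits are not)."""
    cfg = SynthConfig(n_participants=8000, seed=11, baseline_mortality_rate=0.01)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared8k(cohort8k) -> pd.DataFrame:
    df = cohort8k.copy()
    for col, name in (("sleep_h", "sleep"), ("mvpa_min", "mvpa"), ("dqs", "dqs")):
        df[f"{col}_w"] = winsorise(df[col])
        _, df[f"{name}_t"] = assign_tertiles(df[f"{col}_w"], name)
    df["joint_category"] = make_joint_categories(df["sleep_t"], df["mvpa_t"],
                                                 df["dqs_t"])
    return disease_free_outcome(df)


def random_rate_schedule(rng: np.random.Generator):
    """Random plausible mortality schedule for property tests."""
    from spanlife.lifetable import BaselineRates

    k = int(rng.integers(2, 12))
    width = float(rng.choice([1.0, 5.0]))
    starts = 40.0 + width * np.arange(k)
    widths = np.full(k, width)
    widths[-1] = np.inf
    m = rng.uniform(0.001, 0.3, k)
    return BaselineRates(starts, widths, m)
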