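import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import saqmap as sq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: printed pooled-sample subscale means (0–100) used in the coefficient
#: application identities
SUBSCALE_MEANS = {"pl": 70.83, "as": 36.18, "af": 64.55, "ts": 67.69, "dp": 51.80}


@pytest.fixture(scope="session")
def value_set():
    return sq.load_value_set("china-5L")


@pytest.fixture(scope="session")
def default_config():
    return sq.GeneratorConfig()


@pytest.fixture(scope="session")
def calibration(default_config, value_set):
    return sq.calibrate_thresholds(default_config, value_set)


@pytest.fixture(scope="session")
def cohort(value_set, calibration):
    cfg = sq.GeneratorConfig(seed=11)
    base = sq.generate_cohort(cfg, value_set, calibration=calibration)
    return sq.generate_followup(base, cfg, value_set, calibration=calibration)


@pytest.fixture(scope="session")
def design_and_utility(cohort):
    df = cohort.data
    return sq.build_design(df), df["utility"].to_numpy()


def random_design(n: int, seed: int) -> pd.DataFrame:
    """Uniform subscale scores mapped through the standard design."""
    rng = np.random.default_rng(seed)
    scores = pd.DataFrame({s: rng.uniform(0.0, 100.0, n)
                           for s in ("pl", "as", "af", "ts", "dp")})
    return sq.build_design(scores)


@pytest.fixture
def mean_scores():
    return sq.SAQScores(pl=70.83, as_=36.18, af=64.55, ts=67.69, dp=51.80)
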