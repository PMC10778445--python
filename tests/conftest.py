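import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_trials() -> pd.DataFrame:
    """Deterministic 2-dog cohort, 20 identical trials per session."""
    rows = []
    loads = {
        ("a", "T0"): (32.0, 32.0, 18.0, 18.0),
        ("a", "D15"): (31.0, 31.0, 19.0, 19.0),
        ("b", "T0"): (33.0, 33.0, 15.0, 19.0),
        ("b", "D15"): (31.5, 31.5, 17.5, 19.5),
    }
    for (dog, tp), (lf, rf, lh, rh) in loads.items():
        for k in range(1, 21):
            rows.append((dog, tp, k, lf, rf, lh, rh))
    return pd.DataFrame(
        rows,
        columns=["dog_id", "timepoint", "trial_index", "wb_lf", "wb_rf", "wb_lh", "wb_rh"],
    )


@pytest.fixture
def small_anchors() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dog_id": ["a", "b"],
            "anchor_t0": ["Good", "Good"],
            "anchor_d15": ["Very Good", "Good"],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)
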