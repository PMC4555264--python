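import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mehgtk.tk_model import TKParams

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tk_default() -> TKParams:
    """Kinetic nuisances at the reported posterior means."""
    return TKParams(abs_fraction=0.955, frac_blood=0.089, blood_volume=3.423)


@pytest.fixture()
def tiny_cohort() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    n = 12
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "sex": ["male", "female"] * (n // 2),
            "age": rng.uniform(20, 80, n).round(1),
            "weight_kg": rng.normal(66, 12, n).clip(40, 110),
            "blood_mehg_ug_per_L": rng.lognormal(np.log(5), 0.6, n),
            "intake_ug_per_kg_day": rng.lognormal(np.log(0.031), 0.9, n),
        }
    )
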