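import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dlwsens import SimConfig, simulate_cohort

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def cohort():
    """A default synthetic cohort (n = 120, seed 1)."""
    return simulate_cohort(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def pp_cohort(cohort):
    """The per-protocol (weight-stable) subset of the default cohort."""
    return cohort[cohort["per_protocol"]].reset_index(drop=True)


@pytest.fixture()
def hand_cohort():
    """Six participants with hand-set energy books (stored energy zero).

    Unaccounted energy is exactly intake - TEE: [-300, -100, 0, 100, 300,
    -260] kcal/day.
    """
    tee = np.array([3000.0, 2900.0, 3100.0, 2700.0, 2600.0, 2800.0])
    ue = np.array([-300.0, -100.0, 0.0, 100.0, 300.0, -260.0])
    return pd.DataFrame(
        {
            "id": [f"H{i}" for i in range(6)],
            "arm": ["low", "low", "low", "high", "high", "high"],
            "cohort": [1, 2, 1, 2, 1, 2],
            "tee_post": [2950.0, 2850.0, 3050.0, 2750.0, 2650.0, 2850.0],
            "tee_wk10": tee,
            "tee_wk20": tee,
            "intake_reported": tee + ue,
            "delta_fm": 0.0,
            "delta_ffm": 0.0,
        }
    )
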