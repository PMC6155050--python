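import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_instruments() -> pd.DataFrame:
    """Five harmonised instruments with modest heterogeneity."""
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(5)],
            "gamma_hat": [0.10, 0.08, 0.12, 0.09, 0.11],
            "sigma_x": [0.010, 0.012, 0.009, 0.011, 0.010],
            "Gamma_hat": [0.050, 0.038, 0.062, 0.047, 0.052],
            "sigma_y": [0.020, 0.022, 0.018, 0.021, 0.019],
        }
    )


@pytest.fixture
def het_instruments() -> pd.DataFrame:
    """Twenty instruments with real heterogeneity (phi > 1)."""
    rng = np.random.default_rng(2024)
    j = 20
    gamma = rng.uniform(0.05, 0.2, j)
    sigma_x = rng.uniform(0.004, 0.012, j)
    sigma_y = rng.uniform(0.01, 0.03, j)
    Gamma = 0.25 * gamma + rng.normal(0, 0.05, j)  # large residual scatter
    return pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(j)],
            "gamma_hat": gamma,
            "sigma_x": sigma_x,
            "Gamma_hat": Gamma,
            "sigma_y": sigma_y,
        }
    )
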