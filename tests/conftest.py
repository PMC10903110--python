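import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cytopls as cp

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    return cp.SyntheticConfig(n_per_group=3, n_analytes=6, n_informative=2, seed=11)


@pytest.fixture
def informative_panel():
    """A strongly separable panel with a sparse response map (fixed seed)."""
    cfg = cp.SyntheticConfig(
        n_per_group=8,
        n_analytes=12,
        n_informative=4,
        effect_size=2.0,
        response_coefficients={0: 1.0, 5: -1.0},
        response_noise_sd=0.2,
        seed=42,
    )
    panel = cp.generate_response(cp.generate_panel(cfg), cfg)
    return cfg, panel


@pytest.fixture
def cleaned_scaled(informative_panel):
    _, panel = informative_panel
    matrix = cp.clean_panel(panel)
    return panel, matrix, cp.zscore(matrix.values)


def random_regression_problem(seed, n=20, m=8):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, m)), rng.standard_normal(n)
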