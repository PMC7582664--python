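import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import marshphen as mp
from marshphen.curvefit import eval_model
from marshphen.timeseries import ViSeries

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# Canonical truth curves, one per family, used throughout the recovery tests.
TRUTHS = {
    "AG": {"c1": 0.1, "c2": 0.6, "a1": 200.0, "a2": 45.0, "a3": 60.0, "a4": 2.3},
    "DL": {"c1": 0.1, "c2": 0.5, "a1": 120.0, "a2": 8.0, "a3": 280.0, "a4": 10.0},
    "TF": {"c": 0.4, "w": 2 * np.pi / 365, "a1": -0.25, "b1": 0.12,
           "a2": 0.12, "b2": -0.10},
}


@pytest.fixture(scope="session")
def irregular_days():
    """40 irregular observation days, fixed across the whole suite."""
    rng = np.random.default_rng(42)
    return np.sort(rng.uniform(1.0, 365.0, 40))


@pytest.fixture
def make_series(irregular_days):
    """Factory: noise-free ViSeries generated from a named family's truth."""
    def _make(method, noise_sigma=0.0, seed=0, days=None):
        days = irregular_days if days is None else days
        values = eval_model(method, TRUTHS[method], days)
        if noise_sigma > 0:
            rng = np.random.default_rng(seed)
            values = values + rng.normal(0.0, noise_sigma, len(days))
        return ViSeries("px", days, values, "NDVI")
    return _make


@pytest.fixture
def template():
    return mp.PhenologyTemplate("veg", base_level=0.15, amplitude=0.5,
                                peak_day=220, green_up_width=50,
                                senescence_width=60)
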