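import numpy as np
import pytest

from glucodyn.cohort import GTT_GRID_MIN, CohortConfig, generate_cohort
from glucodyn.dynamics import ToleranceTestSeries, damped_oscillation


@pytest.fixture(scope="session")
def gtt_grid_h():
    return np.asarray(GTT_GRID_MIN, dtype=float) / 60.0


@pytest.fixture(scope="session")
def reference_params():
    """Generating parameters of the canonical noiseless test curve."""
    return dict(G0=100.0, A=80.0, alpha=0.8, T=3.0, phi=0.2)


@pytest.fixture(scope="session")
def noiseless_series(gtt_grid_h, reference_params):
    y = damped_oscillation(gtt_grid_h, **reference_params)
    return ToleranceTestSeries("ref", "GTT", 0, gtt_grid_h, y)


@pytest.fixture(scope="session")
def zero_noise_cohort():
    cfg = CohortConfig(noise_sd_mgdl=0.0, animal_effect_cv=0.0, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(seed=5))


def draw_params(rng):
    """One generating-parameter draw from the identifiable physiological region."""
    return dict(
        G0=rng.uniform(70.0, 200.0),
        A=rng.uniform(20.0, 120.0),
        alpha=rng.uniform(0.2, 2.5),
        T=rng.uniform(2.0, 8.0),
        phi=rng.uniform(-1.0, 1.0),
    )
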