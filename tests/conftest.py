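import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import labelkin as lk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def toy_hist():
    """edges {1,10,100,1000}, counts [5,7,9], threshold 10."""
    return lk.FluorescenceHistogram([1, 10, 100, 1000], [5, 7, 9], 10.0, "toy")


@pytest.fixture(scope="session")
def paper_like_experiment():
    """Synthetic two-population experiment at the study's fitted values."""
    return lk.generate_experiment(
        lk.paper_like_truth(seed=7), horizons=(168.0, 504.0),
        n_acquire=10_000, founders=10_000,
    )


def point_division_model(tau: float) -> lk.ProliferationModel:
    """Single proliferating population with a deterministic cycle time."""
    sp = lk.Subpopulation(
        "proliferating",
        mean_bounds=(tau, tau),
        sd_bounds=(0.01, 40.0),
        proportion=1.0,
        law=lk.DivisionLaw(tau, 1.0, tau, tau),
    )
    return lk.ProliferationModel(1, (sp,))


def single_founder_histogram(f0: float, threshold: float = 0.0) -> lk.FluorescenceHistogram:
    """One count in a vanishingly narrow bin around ``f0``."""
    eps = 1e-12
    return lk.FluorescenceHistogram(
        [f0 * (1 - eps), f0 * (1 + eps)], [1.0], threshold
    )
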