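import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def manchester():
    from petasym.kinetics import manchester_schedule

    return manchester_schedule()


@pytest.fixture(scope="session")
def turku():
    from petasym.kinetics import turku_schedule

    return turku_schedule()


@pytest.fixture(scope="session")
def reference_tac(manchester):
    from petasym.simulate import simulate_reference_tac

    return simulate_reference_tac(manchester, amp=50.0, lam1=0.05, lam2=0.5)


@pytest.fixture(scope="session")
def small_config():
    """A 14-subject two-centre cohort: quick but statistically non-trivial."""
    from petasym.simulate import CohortConfig

    return CohortConfig(n_per_centre={"Manchester": 8, "Turku": 6}, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20251)
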