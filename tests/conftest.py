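import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def v9_scheme():
    from fuzzysel.datasets import sonar_v9_scheme

    return sonar_v9_scheme()


@pytest.fixture
def v9_verdicts():
    from fuzzysel.datasets import sonar_v9_verdicts

    return sonar_v9_verdicts()


@pytest.fixture
def toy_table():
    """4 objects, 2 attributes, 2 classes; x1 separates the classes."""
    from fuzzysel import DecisionTable

    return DecisionTable(
        values=np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]]),
        attributes=("x1", "x2"),
        decision=np.array(["A", "A", "B", "B"]),
    )


def random_binary_table(rng, max_m=12, max_n=8):
    """Helper for selection property tests."""
    from fuzzysel import BinaryTable

    m = int(rng.integers(1, max_m + 1))
    n = int(rng.integers(1, max_n + 1))
    return BinaryTable(
        matrix=rng.integers(0, 2, size=(m, n)),
        attributes=tuple(f"a{j}" for j in range(n)),
        objects=tuple(range(m)),
    )
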