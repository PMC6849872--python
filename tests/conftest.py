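import numpy as np
import pytest

from myogape import canonical_fiber_scenarios, generate_skull


@pytest.fixture(scope="session")
def scene():
    """Default synthetic specimen, shared read-only across tests."""
    return generate_skull()


@pytest.fixture(scope="session")
def scenarios():
    return canonical_fiber_scenarios()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
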