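import numpy as np
import pytest

from tissueheal.params import MaterialParams, biaxial_params


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def params() -> MaterialParams:
    """Biaxial-test parameter set (the most exercised configuration)."""
    return biaxial_params()


def random_unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_admissible_deformation(rng, stretch_scale=0.25):
    """Random deformation gradient with positive determinant, moderate
    stretches, for property tests."""
    F = np.eye(3) + stretch_scale * rng.normal(size=(3, 3)) * 0.5
    if np.linalg.det(F) <= 0.1:
        F = np.eye(3) + 0.05 * rng.normal(size=(3, 3))
    return F
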