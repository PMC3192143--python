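import numpy as np
import pytest

from vda.core import PredictionMatrix


@pytest.fixture
def small_matrix() -> PredictionMatrix:
    """Four instances, three fingerprints: (0,0), (0,1) x2, (1,1)."""
    return PredictionMatrix(
        instance_ids=("w", "x", "y", "z"),
        algorithm_ids=("A", "B"),
        calls=np.array([[0, 0], [0, 1], [0, 1], [1, 1]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20111012)
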