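import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ilrmr import AssociationMatrix, SimilarityMatrix, SynthConfig, generate_network

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_net():
    """The standard planted 40x25 network (rank 3, density 0.12), seed 1."""
    return generate_network(SynthConfig(seed=1))


@pytest.fixture
def toy_assoc():
    """3x3 toy association matrix with every degenerate case reachable."""
    values = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    return AssociationMatrix(values, ["m1", "m2", "m3"], ["d1", "d2", "d3"])


def make_similarity(values, ids, kind):
    return SimilarityMatrix(np.asarray(values, dtype=float), ids, kind)
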