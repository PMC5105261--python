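import numpy as np
import pytest
from hypothesis import settings

from drabal.model import BaseClassifierSpec
from drabal.simulate import GeneratorSpec, generate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rf_small():
    """Fast random-forest base spec for tests that exercise wiring, not accuracy."""
    return BaseClassifierSpec("random_forest", {"n_estimators": 40}, seed=11)


@pytest.fixture
def chain_dataset():
    """Three labels in a chain 0 -> 1 -> 2, strong coupling, 30% missing."""
    spec = GeneratorSpec(
        n_compounds=600, n_features=24, n_labels=3, dag=[(0, 1), (1, 2)],
        coupling=0.8, missing_rate=0.3, seed=5, root_intercepts=[-1.0, -1.0, -1.0],
    )
    dataset, truth = generate(spec)
    return dataset, truth


@pytest.fixture
def tiny_labels():
    """4 x 2 label matrix with one missing entry."""
    return np.array([[1, -1], [-1, 1], [1, 0], [-1, -1]], dtype=np.int8)
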