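import numpy as np
import pytest

from physioact import FeatureRegistry, generate_cohort, generate_session


@pytest.fixture(scope="session")
def session60():
    """One subject, 4 x 60 s segments: long enough for every stream."""
    return generate_session("T1", segment_s=60.0, seed=123)


@pytest.fixture(scope="session")
def cohort3():
    """Three subjects with 4 x 40 s segments: 16 decisions each."""
    return generate_cohort(3, segment_s=40.0, seed=9)


@pytest.fixture(scope="session")
def registry():
    return FeatureRegistry()


@pytest.fixture(scope="session")
def planted_table():
    """20-feature table where features 0-2 are noisy linear functions of a
    4-class label and the remaining 17 are pure noise."""
    rng = np.random.default_rng(42)
    n = 200
    y = rng.integers(0, 4, n)
    X = rng.normal(size=(n, 20))
    for j in range(3):
        X[:, j] += (y == j) * 2.0
    return X, y
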