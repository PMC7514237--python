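import numpy as np
import pytest

import intervalpca as ip


def random_interval_matrix(rng: np.random.Generator, n: int, m: int,
                           width_scale: float = 1.0) -> ip.IntervalMatrix:
    """A small random interval matrix with Gaussian centers."""
    centers = rng.normal(scale=2.0, size=(n, m))
    half = 0.5 * width_scale * np.abs(rng.normal(size=(n, m)))
    return ip.IntervalMatrix(centers - half, centers + half)


def random_realization(rng: np.random.Generator, X: ip.IntervalMatrix) -> ip.RealizationMatrix:
    t = rng.uniform(size=X.lower.shape)
    return X.realize(X.lower + t * (X.upper - X.lower))


@pytest.fixture(scope="session")
def faces() -> ip.IntervalMatrix:
    return ip.load_faces()


@pytest.fixture(scope="session")
def faces_center(faces):
    return ip.IntervalPCA(faces, method="center", sign_anchors=("X4", "X3")).fit()


@pytest.fixture(scope="session")
def faces_vertex(faces):
    return ip.IntervalPCA(faces, method="vertex", sign_anchors=("X4", "X3")).fit()


@pytest.fixture(scope="session")
def faces_compare(faces):
    """All four methods fitted once on the faces data (Best Point runs are
    the expensive part; shared across tests)."""
    return ip.compare(faces, sign_anchors=("X4", "X3"))
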