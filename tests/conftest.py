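import numpy as np
import pytest

from rscukit import standard_genetic_code
from rscukit.simulate import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def code():
    return standard_genetic_code()


@pytest.fixture(scope="session")
def small_study():
    """A compact planted study shared by read-only tests."""
    return generate_study(SyntheticConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def grid_clusters(seed=0, jitter=0.05):
    """Two dense jittered-grid clusters plus four far background outliers.

    The canonical density-clustering regime: near-constant within-cluster
    nearest-neighbor distances give the k-distance curve a sharp knee, and
    the outliers are genuine noise.  Truth labels the outliers -1."""
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid(np.arange(6), np.arange(5))
    grid = np.c_[gx.ravel(), gy.ravel()].astype(float)
    a = grid + [-13, 0] + rng.normal(0, jitter, grid.shape)
    b = grid + [8, 0] + rng.normal(0, jitter, grid.shape)
    outliers = np.array([[-2.5, 25.0], [-2.5, -25.0], [30.0, 12.0], [-35.0, -12.0]])
    X = np.vstack([a, b, outliers])
    truth = np.r_[np.zeros(30, int), np.ones(30, int), -np.ones(4, int)]
    return X, truth


def two_blobs(n_per=30, sep=10.0, sigma=1.0, dim=2, seed=0):
    """Two spherical Gaussian clouds, centers symmetric about the origin,
    `sep` standard deviations apart (mimicking centered PCA scores)."""
    rng = np.random.default_rng(seed)
    half = sep * sigma / 2.0
    a = rng.normal(0.0, sigma, (n_per, dim)) + np.r_[-half, np.zeros(dim - 1)]
    b = rng.normal(0.0, sigma, (n_per, dim)) + np.r_[half, np.zeros(dim - 1)]
    X = np.vstack([a, b])
    labels = np.r_[np.zeros(n_per, dtype=int), np.ones(n_per, dtype=int)]
    return X, labels
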