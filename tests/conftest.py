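import numpy as np
import pytest

import leafsurf as ls


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _random_surface(rng, n_u=4, n_v=5, degree=2, rational=True):
    """A smooth random tensor-product surface for oracle tests."""
    xs = np.sort(rng.uniform(0, 10, n_u))
    ys = np.sort(rng.uniform(0, 10, n_v))
    net = np.empty((n_u, n_v, 3))
    net[:, :, 0] = xs[:, None] + rng.normal(0, 0.3, (n_u, n_v))
    net[:, :, 1] = ys[None, :] + rng.normal(0, 0.3, (n_u, n_v))
    net[:, :, 2] = rng.normal(0, 1.5, (n_u, n_v))
    ku = ls.knots_from_params(np.sort(np.concatenate(
        [[0.0], rng.uniform(0.05, 0.95, n_u - 2), [1.0]])), degree, n_u)
    kv = ls.knots_from_params(np.sort(np.concatenate(
        [[0.0], rng.uniform(0.05, 0.95, n_v - 2), [1.0]])), degree, n_v)
    w = rng.uniform(0.5, 2.0, (n_u, n_v)) if rational else None
    return ls.NurbsSurface(degree, degree, ku, kv, net, w)


@pytest.fixture()
def random_surface_factory():
    return _random_surface


@pytest.fixture(scope="session")
def noisy_leaf():
    """Case-study style scan: 40k points, 0.15 mm noise, 60 mm leaf."""
    spec = ls.LeafSpec(length=60.0, n_points=40_000, noise_sd=0.15, seed=2)
    cloud, truth = ls.generate_leaf(spec)
    return cloud, truth, spec


@pytest.fixture(scope="session")
def clean_leaf():
    """Noiseless leaf for recovery tests."""
    spec = ls.LeafSpec(length=60.0, n_points=40_000, noise_sd=0.0, seed=4)
    cloud, truth = ls.generate_leaf(spec)
    return cloud, truth, spec


@pytest.fixture(scope="session")
def clean_slpc(clean_leaf):
    return ls.pca_normalize(clean_leaf[0])


@pytest.fixture(scope="session")
def case_study_model(noisy_leaf):
    """Default pipeline fitted once and shared across read-only tests."""
    return ls.LeafSurfaceModel().fit(noisy_leaf[0])
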