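import numpy as np
import pytest

from trifase.kernel import SpatialKernel, build_kernel
from trifase.model import CoclusterModel, Indicator


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_instance(rng, n=6, p=8, K=2, R=3, spatial=True, phi=1.5, tau=1.0):
    """Small random fitting problem: data, coordinates, kernel and a valid model."""
    X = rng.standard_normal((n, p)) * 2.0
    coords = rng.random((p, 2)) * 4.0
    if spatial:
        kernel = build_kernel(coords, phi, tau)
    else:
        kernel = SpatialKernel.identity(p, tau)
    rows = Indicator(rng.integers(0, K, n), K)
    cols = Indicator(rng.integers(0, R, p), R)
    mu = rng.standard_normal((K, R))
    model = CoclusterModel(rows=rows, cols=cols, mu=mu, tau=tau, phi=phi)
    return X, coords, kernel, model


def whitened_loss_oracle(X, model, kernel):
    """Reference loss via an explicit matrix inverse (independent of the
    triangular-solve implementation path)."""
    residual = X - model.predicted()
    L_inv = np.linalg.inv(kernel.chol_lower)
    return float(np.linalg.norm(residual @ L_inv.T, "fro") ** 2)
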