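import numpy as np
import pytest

from marstab import MARParameters

LN_TOTAL = np.log(3.5e8)   # the worked stationary log abundance


@pytest.fixture(scope="session")
def two_group_params() -> MARParameters:
    """Two-group (Lactobacillus vs rest) fixture.

    B is the printed woman-60 interaction matrix; A is reconstructed so
    that both groups' stationary-mean log abundance equals ln(3.5e8)
    (A and Sigma are synthetic reconstructions, not reported values).
    """
    B = np.array([[0.86, -0.39], [0.001, 0.76]])
    A = (np.eye(2) - B) @ np.full(2, LN_TOTAL)
    return MARParameters(A=A, B=B, Sigma=0.01 * np.eye(2),
                         taxa=("Lactobacillus", "other"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stationary_params(rng, p, radius=0.9, taxa=None):
    """Random MARParameters with spectral radius scaled below `radius`."""
    B = rng.normal(size=(p, p))
    rho = np.max(np.abs(np.linalg.eigvals(B)))
    B *= radius * rng.uniform(0.3, 1.0) / rho
    L = rng.normal(size=(p, p)) * 0.3
    Sigma = L @ L.T + 0.01 * np.eye(p)
    A = rng.normal(size=p)
    return MARParameters(A=A, B=B, Sigma=Sigma, taxa=taxa)
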