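import numpy as np
import pytest

from phenomv.mixture import FactorCovariance, MixtureParams
from phenomv.tables import UVResultTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_uv():
    """2 phenotypes x 3 lines with one missing cell."""
    return UVResultTable(
        phenotypes=["p1", "p2"],
        lines=["g1", "g2", "g3"],
        centre_of_line={"g1": "C1", "g2": "C1", "g3": "C2"},
        estimate=np.array([[1.0, -0.5, 2.0], [0.3, np.nan, -1.2]]),
        se=np.array([[0.5, 0.4, 0.6], [0.2, np.nan, 0.3]]),
        is_null_line=np.array([False, False, True]),
    )


def make_params(P=3, M=2, S=1, seed=0, rho_R=0.0):
    """Arbitrary valid MixtureParams for posterior/likelihood tests."""
    rng = np.random.default_rng(seed)
    sigmas = []
    for _ in range(S):
        W = rng.normal(size=(P, max(1, P - 1)))
        C = W @ W.T + np.diag(0.3 + rng.random(P))
        from phenomv.mixture import fit_factor_covariance

        sigmas.append(fit_factor_covariance(C, max(1, P - 2)))
    pi = rng.random((M, S)) + 0.2
    pi /= pi.sum()
    omega = np.sort(0.5 + rng.random(M) * 3.0)
    while np.any(np.diff(omega) <= 0):
        omega = np.sort(0.5 + rng.random(M) * 3.0)
    R = np.full((P, P), rho_R) + (1 - rho_R) * np.eye(P)
    return MixtureParams(sigmas=sigmas, pi=pi, omega=omega, R=R)


@pytest.fixture
def arbitrary_params():
    return make_params()
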