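import numpy as np
import pytest

from mpcmr import fit_fpca, simdata


@pytest.fixture(scope="session")
def sim_b3():
    """One moderate simulated cohort: linear genetic effects, increasing
    causal effect (used by several estimation and inference tests)."""
    cfg = simdata.SimConfig(
        n_subjects=2000, exposure_scenario="B", outcome_scenario=3, seed=42
    )
    return simdata.simulate(cfg)


@pytest.fixture(scope="session")
def fpca_b3(sim_b3):
    return fit_fpca(sim_b3.exposure, K=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_linear_iv(
    rng: np.random.Generator,
    n: int = 2000,
    J: int = 10,
    L: int = 2,
    beta=None,
    alpha_scale: float = 0.4,
    noise: float = 1.0,
    confounded: bool = False,
):
    """Small direct linear IV design (no trajectories) for oracle tests.

    E = Z A + V, y = E beta + u with strong first stage by default.
    """
    beta = np.full(L, 0.5) if beta is None else np.asarray(beta, dtype=float)
    Z = rng.binomial(2, 0.3, size=(n, J)).astype(float)
    A = rng.normal(0, alpha_scale, size=(J, L))
    V = rng.normal(0, 1, size=(n, L))
    u = rng.normal(0, noise, size=n)
    if confounded:
        c = rng.normal(0, 1, size=n)
        V = V + c[:, None]
        u = u + 2.0 * c
    E = Z @ A + V
    y = E @ beta + u
    return Z, E, y, beta
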