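"""Shared fixtures: small deterministic harmonized sets and synthetic studies."""

import numpy as np
import pytest
from hypothesis import settings

from mrpath.simulate import SimulationConfig, simulate_study
from mrpath.sumstats import HarmonizedSet

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)


def make_hs(seed: int, k: int = 20, beta: float = 0.3,
            intercept: float = 0.0, noise: float = 1.0) -> HarmonizedSet:
    """Small harmonized set with true slope ``beta`` (+ optional pleiotropy
    intercept on the outcome side) and per-SNP noise scaling."""
    r = np.random.default_rng(seed)
    bx = r.uniform(0.05, 0.2, k) * r.choice([-1, 1], k)
    sx = r.uniform(0.003, 0.008, k)
    sy = r.uniform(0.01, 0.04, k)
    by = intercept * np.sign(bx) + beta * bx + noise * r.normal(0, sy)
    return HarmonizedSet.from_arrays(bx, sx, by, sy)


@pytest.fixture(scope="session")
def hs20():
    """20-SNP harmonized set, true slope 0.3, realistic noise."""
    return make_hs(seed=11, k=20)


@pytest.fixture(scope="session")
def hs_homogeneous():
    """Every Wald ratio exactly 0.3 (no noise): the degenerate reference."""
    return make_hs(seed=12, k=6, noise=0.0)


@pytest.fixture(scope="session")
def clean_study():
    """Default clean-mediation synthetic study (alpha .5, gamma .4, theta .1)."""
    return simulate_study(SimulationConfig(seed=20240101))


@pytest.fixture(scope="session")
def null_study():
    return simulate_study(SimulationConfig(theta=0.0, alpha=0.0, gamma=0.0,
                                           seed=20240104))
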