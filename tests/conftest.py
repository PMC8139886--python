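"""Shared fixtures: the two example networks and randomized-state helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scpw

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bimodal_moments() -> scpw.NetworkMoments:
    """Moments of the bimodal example network: half degree 3, half degree 5."""
    return scpw.moments_from_sequence([3] * 5000 + [5] * 5000)


@pytest.fixture(scope="session")
def bimodal_constants(bimodal_moments) -> scpw.ModelConstants:
    return scpw.derived_constants(bimodal_moments)


@pytest.fixture(scope="session")
def poisson_moments() -> scpw.NetworkMoments:
    """Analytic moments of the Poisson mean-10 example network."""
    return scpw.moments_from_distribution(scpw.poisson_distribution(10.0))


@pytest.fixture(scope="session")
def poisson_constants(poisson_moments) -> scpw.ModelConstants:
    return scpw.derived_constants(poisson_moments)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


def random_nondim_state(rng: np.random.Generator, w_max: float = 0.95) -> scpw.NondimState:
    """A valid (v, w, x, y, z) state with x + y bounded away from zero."""
    w = rng.uniform(1e-3, w_max)
    a, b, c = rng.uniform(0.05, 1.0, size=3)
    total = 2 * a + b + c
    return scpw.NondimState(1 - w, w, a / total, b / total, c / total)


def random_feasible_moments(rng: np.random.Generator) -> scpw.NetworkMoments:
    """Moments of a random discrete degree distribution (hence feasible)."""
    n = rng.integers(3, 8)
    support = np.sort(rng.choice(np.arange(1, 40), size=n, replace=False))
    mass = rng.dirichlet(np.ones(n))
    dist = scpw.DegreeDistribution(tuple(int(k) for k in support), tuple(mass / mass.sum()))
    return scpw.moments_from_distribution(dist)
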