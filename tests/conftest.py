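"""Shared fixtures: tiny hand-checkable systems and random-model factories."""

import numpy as np
import pytest

from elanet import GeneratorConfig, SystemModel, make_model


def pair_model(h1: float, h2: float, j12: float) -> SystemModel:
    """Two-channel system; the smallest landscape with competing minima."""
    return SystemModel(
        n_regions=2,
        h=np.array([h1, h2], dtype=float),
        j=np.array([[0.0, j12], [j12, 0.0]]),
    )


def random_model(n: int, seed: int, scale: float = 0.5) -> SystemModel:
    """Dense random system with parameters ~ U[-scale, scale]."""
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    j = np.zeros((n, n))
    j[iu] = rng.uniform(-scale, scale, iu[0].size)
    j = j + j.T
    return SystemModel(n_regions=n, h=rng.uniform(-scale, scale, n), j=j)


@pytest.fixture
def square_model() -> SystemModel:
    """H=(1,1), J12=-3: energies (0, -1, -1, 1); two equal-depth minima."""
    return pair_model(1.0, 1.0, -3.0)


@pytest.fixture
def tilted_square_model() -> SystemModel:
    """H=(1.2,1.0), J12=-3: energies (0, -1.2, -1.0, 0.8); minima 10 and 01."""
    return pair_model(1.2, 1.0, -3.0)


@pytest.fixture
def community_model() -> SystemModel:
    """Default two-community N=8 system (seed 1): multistable landscape
    with complementary minima pairs."""
    return make_model(GeneratorConfig(n_regions=8, seed=1))


@pytest.fixture(params=[1, 2, 3])
def community_model_seeded(request) -> SystemModel:
    return make_model(GeneratorConfig(n_regions=8, seed=request.param))
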