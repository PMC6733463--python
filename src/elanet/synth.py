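"""Ground-truth model and binary time-series generators.

The generators emulate the statistical regime the landscape analysis
targets: a modest number of binary channels (N ~ 8-19), mostly positive
couplings with a two-community organization, and marginal activation
probabilities near one half (the regime produced by binarizing
globally-regressed signals at zero).  Near that complement-symmetric
point the energy landscape develops pairs of mutually complementary
local minima, which is the phenomenology downstream modules are tested
against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from elanet.errors import ValidationError
from elanet.mem import SystemModel, StateTimeSeries, boltzmann_distribution

STRUCTURES = ("random", "two_community", "ferromagnetic")


@dataclass
class GeneratorConfig:
    """Recipe for a ground-truth model.

    ``h_scale`` and ``j_scale`` are the standard deviations of the field
    and coupling draws, and ``j_density`` the fraction of pairs actually
    coupled (the rest are set to zero, mirroring the heterogeneity of
    fitted interaction matrices; a dense two-community system is
    gauge-equivalent to an unfrustrated ferromagnet with exactly one
    complementary minima pair, whereas sparse couplings support the
    multistable, multi-pair landscapes the analysis targets).
    ``center_h`` places the fields at the complement-symmetric point
    H_i = -(1/2) sum_j J_ij plus the random perturbation, so that state
    marginals sit near 0.5 (mimicking binarization at zero after global
    regression); with ``center_h=False`` fields are drawn around zero
    instead.
    """

    n_regions: int
    structure: str = "two_community"
    h_scale: float = 0.05
    j_scale: float = 0.6
    j_density: float = 0.5
    community_assignment: np.ndarray | None = None
    seed: int = 0
    center_h: bool = True

    def __post_init__(self) -> None:
        if not 2 <= self.n_regions <= 20:
            raise ValidationError("n_regions must be in [2, 20]")
        if self.structure not in STRUCTURES:
            raise ValidationError(
                f"structure must be one of {STRUCTURES}, got {self.structure!r}"
            )
        if self.h_scale < 0 or self.j_scale < 0:
            raise ValidationError("scales must be >= 0")
        if not 0 <= self.j_density <= 1:
            raise ValidationError("j_density must be in [0, 1]")
        if self.community_assignment is not None:
            self.community_assignment = np.asarray(self.community_assignment)
            if self.community_assignment.size != self.n_regions:
                raise ValidationError("community_assignment length must equal N")


def _default_communities(n: int) -> np.ndarray:
    """First half community 0, second half community 1."""
    return (np.arange(n) >= n // 2).astype(int)


def make_model(config: GeneratorConfig) -> SystemModel:
    """Draw a ground-truth model; deterministic given ``config.seed``.

    Structures:

    - ``random``: couplings i.i.d. Normal(0, j_scale).
    - ``two_community``: |Normal(0, j_scale)| within each community,
      -|Normal(0, j_scale)| between communities, which (after a gauge
      flip of one community) is an unfrustrated ferromagnet whose two
      ground states are the complementary community-aligned patterns.
    - ``ferromagnetic``: all couplings |Normal(0, j_scale)|.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_regions
    iu = np.triu_indices(n, k=1)

    draws = rng.normal(0.0, config.j_scale, iu[0].size)

    if config.structure == "random":
        vals = draws
    elif config.structure == "ferromagnetic":
        vals = np.abs(draws)
    else:  # two_community
        comm = (
            config.community_assignment
            if config.community_assignment is not None
            else _default_communities(n)
        )
        same = comm[iu[0]] == comm[iu[1]]
        vals = np.where(same, np.abs(draws), -np.abs(draws))

    vals = vals * (rng.random(iu[0].size) < config.j_density)

    j = np.zeros((n, n))
    j[iu] = vals
    j = j + j.T

    h_noise = rng.normal(0.0, config.h_scale, n)
    if config.center_h:
        h = -0.5 * j.sum(axis=1) + h_noise
    else:
        h = h_noise
    return SystemModel(n_regions=n, h=h, j=j)


def sample_exact(model: SystemModel, n_samples: int, seed: int = 0) -> StateTimeSeries:
    """I.i.d. samples from the Boltzmann distribution via inverse CDF."""
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    probs = boltzmann_distribution(model).probs
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    rng = np.random.default_rng(seed)
    codes = np.searchsorted(cdf, rng.random(n_samples), side="right")
    n = model.n_regions
    states = ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)
    return StateTimeSeries(states=states)


def sample_gibbs(
    model: SystemModel,
    n_samples: int,
    burn_in: int = 1000,
    thin: int = 1,
    seed: int = 0,
) -> StateTimeSeries:
    """Single-site Gibbs sampler with sequential sweeps over channels.

    Each sweep visits channels 0..N-1 in order and resamples
    sigma_i ~ Bernoulli(logistic(H_i + sum_j J_ij sigma_j)).  The state
    after every ``thin``-th post-burn-in sweep is recorded, yielding a
    temporally correlated surrogate for an empirical state sequence.
    """
    if burn_in < 0 or thin < 1 or n_samples < 1:
        raise ValidationError("need burn_in >= 0, thin >= 1, n_samples >= 1")
    n = model.n_regions
    rng = np.random.default_rng(seed)
    total_sweeps = burn_in + n_samples * thin
    u = rng.random((total_sweeps, n))
    state = (rng.random(n) < 0.5).astype(np.int8)
    h, j = model.h, model.j
    out = np.empty((n_samples, n), dtype=np.int8)
    k = 0
    for sweep in range(total_sweeps):
        us = u[sweep]
        for i in range(n):
            field = h[i] + j[i] @ state
            state[i] = us[i] < 1.0 / (1.0 + np.exp(-field))
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            out[k] = state
            k += 1
    return StateTimeSeries(states=out)


def sample_surrogate_continuous(
    model: SystemModel,
    n_samples: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    burn_in: int = 1000,
    thin: int = 1,
) -> np.ndarray:
    """Continuous surrogate signals recoverable by thresholding at zero.

    Binary Gibbs states are mapped to +/-1 and jittered with centered
    Gaussian noise, emulating the zero-threshold binarization step applied
    to real recordings.
    """
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    series = sample_gibbs(model, n_samples, burn_in=burn_in, thin=thin, seed=seed)
    rng = np.random.default_rng(seed + 1)
    signal = series.states.astype(float) * 2.0 - 1.0
    return signal + rng.normal(0.0, noise_sd, signal.shape)


def binarize_series(continuous, threshold: float = 0.0) -> StateTimeSeries:
    """Threshold a continuous T x N table: value > threshold -> 1, else 0.

    A value exactly at the threshold maps to 0 (deactive).
    """
    try:
        arr = np.asarray(continuous, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric entries in continuous input: {exc}")
    if arr.ndim != 2:
        raise ValidationError("continuous input must be a T x N table")
    if not np.isfinite(arr).all():
        raise ValidationError("continuous input contains non-finite entries")
    return StateTimeSeries(states=(arr > threshold).astype(np.int8))
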