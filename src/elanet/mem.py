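"""Pairwise maximum-entropy (Ising) model core.

The model assigns every N-bit activity pattern V = (sigma_1, ..., sigma_N),
sigma_i in {0, 1}, an energy

    E(V) = - sum_i H_i sigma_i - sum_{i<j} J_ij sigma_i sigma_j

and a Boltzmann probability p(V) proportional to exp(-E(V)).  H_i is the
baseline activation tendency of channel i and J_ij the symmetric pairwise
interaction.  The pairwise model is the maximum-entropy distribution
matching the empirical first moments <sigma_i> and second moments
<sigma_i sigma_j>; the independent (first-order) model matches only the
first moments.  All expectations are computed by exact enumeration of the
2**N states, which restricts N to at most 20.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from elanet.errors import (
    DegenerateMomentError,
    EnumerationLimitError,
    UndefinedRatioError,
    ValidationError,
)

#: Hard cap on N for any operation that enumerates all 2**N states.
ENUMERATION_LIMIT = 20


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class BinaryState:
    """An N-channel binary activity pattern with its integer encoding.

    Channel 0 maps to the least-significant bit of ``code``.
    """

    bits: np.ndarray
    code: int

    @classmethod
    def from_bits(cls, bits) -> "BinaryState":
        bits = _as_bits(bits)
        return cls(bits=bits, code=encode_state(bits))

    @classmethod
    def from_code(cls, code: int, n: int) -> "BinaryState":
        return cls(bits=decode_state(code, n), code=int(code))

    @property
    def n(self) -> int:
        return self.bits.size


@dataclass
class SystemModel:
    """Parameters (H, J) of a pairwise maximum-entropy model.

    ``j`` is symmetric with an exactly zero diagonal; ``h`` has one entry
    per channel (brain region, neuron, ...).
    """

    n_regions: int
    h: np.ndarray
    j: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.j = np.asarray(self.j, dtype=float)
        n = int(self.n_regions)
        if n < 1:
            raise ValidationError("n_regions must be >= 1")
        if self.h.shape != (n,):
            raise ValidationError(f"h must have shape ({n},), got {self.h.shape}")
        if self.j.shape != (n, n):
            raise ValidationError(f"j must have shape ({n},{n}), got {self.j.shape}")
        if not np.allclose(self.j, self.j.T, atol=0.0, rtol=0.0):
            raise ValidationError("j must be exactly symmetric")
        if np.any(np.diag(self.j) != 0.0):
            raise ValidationError("j must have an exactly zero diagonal")
        if self.region_labels is not None and len(self.region_labels) != n:
            raise ValidationError("region_labels length must equal n_regions")


@dataclass
class StateTimeSeries:
    """A T x N matrix of binary samples, one state per row."""

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 2 or self.states.shape[0] < 1:
            raise ValidationError("states must be a non-empty T x N matrix")
        if not np.isin(self.states, (0, 1)).all():
            raise ValidationError("states entries must be 0 or 1")
        self.states = self.states.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_regions(self) -> int:
        return self.states.shape[1]

    def codes(self) -> np.ndarray:
        """Integer code of every row (channel 0 = least-significant bit)."""
        weights = 1 << np.arange(self.n_regions, dtype=np.int64)
        return self.states.astype(np.int64) @ weights


@dataclass
class MomentSet:
    """First and second moments of a binary ensemble.

    ``second`` is symmetric; its diagonal equals ``first`` because
    sigma_i**2 == sigma_i for binary variables.  ``n_samples`` records the
    sample size when the moments are empirical (used for boundary clipping).
    """

    first: np.ndarray
    second: np.ndarray
    n_samples: int | None = None

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        n = self.first.size
        if self.second.shape != (n, n):
            raise ValidationError("second must be N x N")
        if np.any(self.first < 0) or np.any(self.first > 1):
            raise ValidationError("first moments must lie in [0, 1]")


@dataclass
class StateDistribution:
    """A probability vector over all 2**N state codes."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0):
            raise ValidationError("probabilities must be non-negative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValidationError("probabilities must sum to 1 within 1e-12")

    @property
    def n_regions(self) -> int:
        size = self.probs.size
        n = int(round(np.log2(size)))
        if 2**n != size:
            raise ValidationError("probability vector length must be a power of 2")
        return n


@dataclass
class FitResult:
    """Outcome of the gradient-ascent pairwise fit."""

    model: SystemModel
    n_iterations: int
    converged: bool
    final_gradient_norm: float


@dataclass
class FitMetrics:
    """Goodness-of-fit summary comparing independent and pairwise models.

    d1/d2 are Kullback-Leibler divergences of the empirical distribution
    from the first- and second-order models; s1/s2/sn are the corresponding
    entropies (sn from the empirical distribution itself).  r_d is the
    accuracy (D1-D2)/D1, r_s the entropy ratio (S1-S2)/(S1-SN) and er the
    reliability combining the two (1 for an error-free pairwise fit).
    """

    d1: float
    d2: float
    s1: float
    s2: float
    sn: float
    r_d: float
    r_s: float
    er: float


# ---------------------------------------------------------------------------
# State-space plumbing
# ---------------------------------------------------------------------------

def _as_bits(bits) -> np.ndarray:
    arr = np.asarray(bits)
    if arr.ndim != 1:
        raise ValidationError("a state must be a 1-D bit vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("state entries must be 0 or 1")
    return arr.astype(np.int8)


def _state_bits(state) -> np.ndarray:
    if isinstance(state, BinaryState):
        return state.bits
    return _as_bits(state)


def _check_enum(n: int) -> None:
    if n > ENUMERATION_LIMIT:
        raise EnumerationLimitError(
            f"N={n} exceeds the exact-enumeration limit of {ENUMERATION_LIMIT}"
        )


def encode_state(bits) -> int:
    """Map a bit vector to its integer code (channel 0 = LSB)."""
    arr = _as_bits(bits)
    if arr.size > ENUMERATION_LIMIT:
        raise ValidationError(f"state length must be <= {ENUMERATION_LIMIT}")
    weights = 1 << np.arange(arr.size, dtype=np.int64)
    return int(arr.astype(np.int64) @ weights)


def decode_state(code: int, n: int) -> np.ndarray:
    """Inverse of :func:`encode_state` for an N-channel system."""
    code = int(code)
    if not 0 <= code < 2**n:
        raise ValidationError(f"code {code} out of range for N={n}")
    return ((code >> np.arange(n)) & 1).astype(np.int8)


def all_states(n: int) -> np.ndarray:
    """The full (2**N, N) state matrix; row k holds the bits of code k."""
    _check_enum(n)
    codes = np.arange(2**n, dtype=np.int64)
    return ((codes[:, None] >> np.arange(n)) & 1).astype(np.int8)


# ---------------------------------------------------------------------------
# Energy and Boltzmann distribution
# ---------------------------------------------------------------------------

def energy(model: SystemModel, state) -> float:
    """Energy of one state: -sum_i H_i s_i - sum_{i<j} J_ij s_i s_j."""
    s = _state_bits(state).astype(float)
    if s.size != model.n_regions:
        raise ValidationError(
            f"state length {s.size} != model n_regions {model.n_regions}"
        )
    # j is symmetric with zero diagonal, so s.j.s double-counts each pair
    return float(-model.h @ s - 0.5 * s @ model.j @ s)


def state_energies(model: SystemModel) -> np.ndarray:
    """Energies of all 2**N states, indexed by state code."""
    _check_enum(model.n_regions)
    s = all_states(model.n_regions).astype(float)
    return -s @ model.h - 0.5 * np.einsum("ki,kj,ij->k", s, s, model.j)


def boltzmann_distribution(model: SystemModel) -> StateDistribution:
    """Exact Boltzmann distribution p(V_k) ~ exp(-E(V_k)) over all codes."""
    e = state_energies(model)
    # log-sum-exp guard against overflow for large |parameters|
    logits = -e
    logits -= logits.max()
    w = np.exp(logits)
    return StateDistribution(probs=w / w.sum())


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def empirical_moments(series: StateTimeSeries) -> MomentSet:
    """Time-averaged first and second moments of a binary series."""
    s = series.states.astype(float)
    first = s.mean(axis=0)
    second = (s.T @ s) / series.n_samples
    return MomentSet(first=first, second=second, n_samples=series.n_samples)


def empirical_distribution(series: StateTimeSeries) -> StateDistribution:
    """Relative frequency of each state code; unseen codes get exactly 0."""
    n = series.n_regions
    _check_enum(n)
    counts = np.bincount(series.codes(), minlength=2**n)
    return StateDistribution(probs=counts / counts.sum())


def model_moments(model: SystemModel) -> MomentSet:
    """Exact expectations <sigma_i> and <sigma_i sigma_j> under the model."""
    p = boltzmann_distribution(model).probs
    s = all_states(model.n_regions).astype(float)
    first = p @ s
    second = s.T @ (s * p[:, None])
    second = 0.5 * (second + second.T)  # symmetrize away rounding noise
    np.fill_diagonal(second, first)
    return MomentSet(first=first, second=second)


def _clipped_targets(
    moments: MomentSet, clip: float | None, check_second: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Clip boundary moments into the open interval (0, 1).

    ``clip=None`` derives epsilon = 1/(2T) from the recorded sample size;
    boundary moments without any usable epsilon raise
    :class:`DegenerateMomentError` because the log-ratio updates diverge
    there.  ``check_second=False`` ignores the second moments (the
    independent fit does not constrain them).
    """
    eps = clip
    if eps is None and moments.n_samples:
        eps = 1.0 / (2.0 * moments.n_samples)
    first = moments.first.copy()
    second = moments.second.copy()
    on_boundary = np.any(first <= 0) or np.any(first >= 1)
    if check_second:
        on_boundary = on_boundary or np.any(second <= 0) or np.any(second >= 1)
    if on_boundary:
        if eps is None:
            raise DegenerateMomentError(
                "a target moment is exactly 0 or 1; supply clip or n_samples"
            )
        first = np.clip(first, eps, 1.0 - eps)
        second = np.clip(second, eps, 1.0 - eps)
    return first, second


def fit_independent_mem(moments: MomentSet, clip: float | None = None) -> SystemModel:
    """Closed-form first-order model: J = 0, H_i = logit(<sigma_i>)."""
    first, _ = _clipped_targets(moments, clip, check_second=False)
    n = first.size
    h = np.log(first / (1.0 - first))
    return SystemModel(n_regions=n, h=h, j=np.zeros((n, n)))


def fit_pairwise_mem(
    moments: MomentSet,
    a_g: float = 0.1,
    tol: float = 1e-5,
    max_iter: int = 500_000,
    clip: float | None = None,
) -> FitResult:
    """Gradient-ascent fit of the pairwise model to target moments.

    Each iteration recomputes the model moments by full enumeration and
    applies the multiplicative log-ratio updates

        H_i  += a_g * log(<sigma_i>        / <sigma_i>_m)
        J_ij += a_g * log(<sigma_i sigma_j> / <sigma_i sigma_j>_m)

    declaring convergence when the largest absolute log-ratio (the
    "gradient") drops below ``tol``.  Non-convergence at ``max_iter`` is
    flagged in the result, not raised.  Initialization is the independent
    solution (H at the logit of the first moments, J = 0).
    """
    t_first, t_second = _clipped_targets(moments, clip)
    n = t_first.size
    _check_enum(n)
    iu = np.triu_indices(n, k=1)
    t2 = t_second[iu]

    s = all_states(n).astype(float)
    pair = s[:, iu[0]] * s[:, iu[1]]  # (2**n, n_pairs)

    h = np.log(t_first / (1.0 - t_first))
    j_flat = np.zeros(t2.size)

    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        e = -s @ h - pair @ j_flat
        logits = -e
        logits -= logits.max()
        w = np.exp(logits)
        p = w / w.sum()
        m1 = p @ s
        m2 = p @ pair
        g1 = np.log(t_first / m1)
        g2 = np.log(t2 / m2)
        grad_norm = max(
            np.abs(g1).max(initial=0.0), np.abs(g2).max(initial=0.0)
        )
        if grad_norm < tol:
            break
        h = h + a_g * g1
        j_flat = j_flat + a_g * g2

    j = np.zeros((n, n))
    j[iu] = j_flat
    j = j + j.T
    model = SystemModel(n_regions=n, h=h, j=j)
    return FitResult(
        model=model,
        n_iterations=it,
        converged=bool(grad_norm < tol),
        final_gradient_norm=float(grad_norm),
    )


# ---------------------------------------------------------------------------
# Fit-quality metrics
# ---------------------------------------------------------------------------

def _kl(p: np.ndarray, q: np.ndarray) -> float:
    """KL divergence sum p log(p/q) in nats, with 0 log 0 = 0."""
    mask = p > 0
    if np.any(q[mask] <= 0):
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _entropy(p: np.ndarray) -> float:
    mask = p > 0
    return float(-np.sum(p[mask] * np.log(p[mask])))


def fit_metrics(
    empirical: StateDistribution,
    independent: SystemModel,
    pairwise: SystemModel,
    er_mode: str = "ratio",
) -> FitMetrics:
    """Accuracy r_D, entropy ratio r_S and reliability ER of a pairwise fit.

    D_k is the KL divergence of the empirical distribution from the k-th
    order model, S_k the model entropy and S_N the empirical entropy;
    r_D = (D1-D2)/D1 and r_S = (S1-S2)/(S1-SN).  Both ratios are invariant
    to the logarithm base; natural logs are used.  ``er_mode`` selects how
    the two are combined into ER: ``"ratio"`` (r_S / r_D, the default) or
    ``"product"`` (r_S * r_D); either equals 1 when the pairwise model
    reproduces the empirical distribution exactly.
    """
    if er_mode not in ("ratio", "product"):
        raise ValidationError("er_mode must be 'ratio' or 'product'")
    p_n = empirical.probs
    p1 = boltzmann_distribution(independent).probs
    p2 = boltzmann_distribution(pairwise).probs
    if not p_n.size == p1.size == p2.size:
        raise ValidationError("distributions and models must share the same N")

    d1 = _kl(p_n, p1)
    d2 = _kl(p_n, p2)
    s1 = _entropy(p1)
    s2 = _entropy(p2)
    sn = _entropy(p_n)

    if d1 == 0.0:
        raise UndefinedRatioError(
            "D1 = 0: the empirical distribution is already first-order"
        )
    if s1 == sn:
        raise UndefinedRatioError("S1 = S_N: entropy ratio undefined")

    r_d = (d1 - d2) / d1
    r_s = (s1 - s2) / (s1 - sn)
    er = r_s / r_d if er_mode == "ratio" else r_s * r_d
    return FitMetrics(d1=d1, d2=d2, s1=s1, s2=s2, sn=sn, r_d=r_d, r_s=r_s, er=er)
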