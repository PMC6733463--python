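"""Core model machinery: encoding, energies, moments, fitting, fit metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elanet import (
    MomentSet,
    StateTimeSeries,
    SystemModel,
    all_states,
    boltzmann_distribution,
    empirical_distribution,
    empirical_moments,
    encode_state,
    decode_state,
    energy,
    fit_independent_mem,
    fit_metrics,
    fit_pairwise_mem,
    model_moments,
)
from elanet.errors import (
    DegenerateMomentError,
    EnumerationLimitError,
    UndefinedRatioError,
    ValidationError,
)
from elanet.synth import sample_exact

from conftest import pair_model, random_model


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "bits,code",
    [((0, 0), 0), ((1, 0), 1), ((0, 1), 2), ((1, 1), 3), ((1, 0, 1, 1), 13)],
)
def test_encode_bit_order_convention(bits, code):
    """Channel 0 maps to the least-significant bit."""
    assert encode_state(bits) == code
    assert np.array_equal(decode_state(code, len(bits)), bits)


def test_encode_decode_bijective_exhaustive():
    for code in range(16):
        assert encode_state(decode_state(code, 4)) == code
    # and the full state matrix agrees row by row
    states = all_states(4)
    for code in range(16):
        assert np.array_equal(states[code], decode_state(code, 4))


@settings(derandomize=True, deadline=None)
@given(st.lists(st.integers(0, 1), min_size=1, max_size=12))
def test_encode_decode_roundtrip_property(bits):
    assert np.array_equal(decode_state(encode_state(bits), len(bits)), bits)


def test_encode_rejects_nonbinary():
    with pytest.raises(ValidationError):
        encode_state([0, 2, 1])


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def test_energy_direct_substitution():
    model = pair_model(1.0, -1.0, 0.5)
    assert energy(model, [1, 1]) == pytest.approx(-0.5)
    assert energy(model, [0, 0]) == 0.0
    assert energy(model, [1, 0]) == pytest.approx(-1.0)
    assert energy(model, [0, 1]) == pytest.approx(1.0)


def test_energy_dimension_mismatch():
    with pytest.raises(ValidationError):
        energy(pair_model(1.0, -1.0, 0.5), [1, 0, 1])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_single_flip_energy_equals_local_field(seed):
    """Flipping bit i changes E by -/+ (H_i + sum_j J_ij s_j)."""
    model = random_model(6, seed)
    rng = np.random.default_rng(seed + 100)
    for _ in range(20):
        s = rng.integers(0, 2, 6)
        i = rng.integers(0, 6)
        flipped = s.copy()
        flipped[i] = 1 - flipped[i]
        local_field = model.h[i] + model.j[i] @ s
        expected = -local_field if flipped[i] == 1 else local_field
        assert energy(model, flipped) - energy(model, s) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Boltzmann distribution
# ---------------------------------------------------------------------------

def test_boltzmann_symmetric_single_channel():
    model = SystemModel(n_regions=1, h=np.zeros(1), j=np.zeros((1, 1)))
    assert np.allclose(boltzmann_distribution(model).probs, [0.5, 0.5])


def test_boltzmann_hand_enumeration():
    # energies over codes 0..3: 0, -1, 1, -0.5
    model = pair_model(1.0, -1.0, 0.5)
    p = boltzmann_distribution(model).probs
    z = 1 + math.e + math.exp(-1) + math.exp(0.5)
    assert p[1] == pytest.approx(math.e / z, abs=1e-12)


def test_boltzmann_overflow_guard():
    model = pair_model(500.0, 500.0, 200.0)
    p = boltzmann_distribution(model).probs
    assert np.isfinite(p).all()
    assert p.sum() == pytest.approx(1.0)
    assert p[3] == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_boltzmann_consistent_with_energies(seed):
    """-log p equals E up to the common log-partition constant."""
    model = random_model(5, seed)
    p = boltzmann_distribution(model).probs
    e = np.array([energy(model, decode_state(c, 5)) for c in range(32)])
    neglogp = -np.log(p)
    assert np.allclose(
        neglogp - neglogp.min(), e - e.min(), atol=1e-9
    )
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_enumeration_limit_enforced():
    n = 21
    model = SystemModel(n_regions=n, h=np.zeros(n), j=np.zeros((n, n)))
    with pytest.raises(EnumerationLimitError):
        boltzmann_distribution(model)


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------

def test_empirical_moments_two_row_average():
    series = StateTimeSeries(states=np.array([[1, 0], [1, 1]]))
    m = empirical_moments(series)
    assert np.allclose(m.first, [1.0, 0.5])
    assert m.second[0, 1] == pytest.approx(0.5)


def test_empirical_moments_constant_series():
    series = StateTimeSeries(states=np.ones((7, 3), dtype=int))
    m = empirical_moments(series)
    assert np.allclose(m.first, 1.0)
    assert np.allclose(m.second, 1.0)


def test_empirical_distribution_counting():
    series = StateTimeSeries(states=np.array([[0, 0], [0, 0], [1, 1], [1, 0]]))
    assert np.allclose(
        empirical_distribution(series).probs, [0.5, 0.25, 0.0, 0.25]
    )


@pytest.mark.parametrize("seed", [3, 4])
def test_empirical_distribution_matches_histogram_oracle(seed):
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 2, size=(500, 3))
    series = StateTimeSeries(states=states)
    # independent counting pass
    counts = np.zeros(8)
    for row in states:
        counts[row[0] + 2 * row[1] + 4 * row[2]] += 1
    assert np.allclose(empirical_distribution(series).probs, counts / 500)


def test_model_moments_single_channel_symmetric():
    model = SystemModel(n_regions=1, h=np.zeros(1), j=np.zeros((1, 1)))
    assert model_moments(model).first[0] == pytest.approx(0.5)


def test_model_moments_factorize_when_independent():
    model = SystemModel(
        n_regions=3, h=np.array([0.3, -0.7, 1.1]), j=np.zeros((3, 3))
    )
    m = model_moments(model)
    for i in range(3):
        for k in range(i + 1, 3):
            assert m.second[i, k] == pytest.approx(m.first[i] * m.first[k])


def test_moments_sampling_agreement():
    """Empirical moments of exact samples approach exact model moments."""
    model = random_model(5, seed=9)
    exact = model_moments(model)
    t = 100_000
    emp = empirical_moments(sample_exact(model, t, seed=9))
    se_first = np.sqrt(exact.first * (1 - exact.first) / t)
    assert np.all(np.abs(emp.first - exact.first) <= 3 * se_first + 1e-12)
    se_second = np.sqrt(exact.second * (1 - exact.second) / t)
    iu = np.triu_indices(5, k=1)
    assert np.all(
        np.abs(emp.second[iu] - exact.second[iu]) <= 3 * se_second[iu] + 1e-12
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def test_independent_fit_closed_form():
    e = math.e
    m = MomentSet(
        first=np.array([0.5, e / (1 + e)]),
        second=np.full((2, 2), 0.25),
    )
    fit = fit_independent_mem(m)
    assert fit.h[0] == pytest.approx(0.0, abs=1e-12)
    assert fit.h[1] == pytest.approx(1.0, abs=1e-12)
    assert np.all(fit.j == 0)


def test_independent_fit_reproduces_first_moments():
    target = model_moments(random_model(4, seed=2))
    fit = fit_independent_mem(target)
    assert np.allclose(model_moments(fit).first, target.first, atol=1e-12)


def test_degenerate_moment_handling():
    m = MomentSet(first=np.array([0.0, 0.5]), second=np.full((2, 2), 0.0))
    with pytest.raises(DegenerateMomentError):
        fit_independent_mem(m)
    # with a sample size the boundary is clipped to 1/(2T) instead
    m_clip = MomentSet(
        first=np.array([0.0, 0.5]), second=np.full((2, 2), 0.0), n_samples=100
    )
    fit = fit_independent_mem(m_clip)
    assert np.isfinite(fit.h).all()


def test_pairwise_fit_recovers_exact_parameters():
    """Fitting on exact moments of a known model recovers H and J."""
    truth = random_model(6, seed=7, scale=1.0)
    result = fit_pairwise_mem(model_moments(truth), tol=1e-7)
    assert result.converged
    assert np.abs(result.model.h - truth.h).max() < 1e-3
    assert np.abs(result.model.j - truth.j).max() < 1e-3


def test_pairwise_fit_fixed_point():
    """Targets from an independent model: the initializer already matches,
    so the fit converges immediately with J = 0."""
    indep = SystemModel(
        n_regions=3, h=np.array([0.4, -0.2, 0.9]), j=np.zeros((3, 3))
    )
    result = fit_pairwise_mem(model_moments(indep))
    assert result.converged
    assert result.n_iterations == 1
    assert np.allclose(result.model.h, indep.h, atol=1e-9)
    assert np.all(result.model.j == 0)


def test_pairwise_fit_moment_matching_at_convergence():
    """At convergence every log-ratio term is below the tolerance."""
    truth = random_model(5, seed=12)
    target = model_moments(truth)
    result = fit_pairwise_mem(target, tol=1e-5)
    fitted = model_moments(result.model)
    assert np.abs(np.log(target.first / fitted.first)).max() < 1e-5
    iu = np.triu_indices(5, k=1)
    assert np.abs(np.log(target.second[iu] / fitted.second[iu])).max() < 1e-5


def test_pairwise_fit_nonconvergence_flagged_not_raised():
    truth = random_model(5, seed=12)
    result = fit_pairwise_mem(model_moments(truth), max_iter=3)
    assert not result.converged
    assert result.n_iterations == 3
    assert result.final_gradient_norm > 1e-5


# ---------------------------------------------------------------------------
# Fit metrics
# ---------------------------------------------------------------------------

def test_fit_metrics_perfect_fit_reliability():
    """Empirical distribution == pairwise Boltzmann distribution -> ER = 1."""
    pairwise = random_model(4, seed=21)
    dist = boltzmann_distribution(pairwise)
    indep = fit_independent_mem(model_moments(pairwise))
    metrics = fit_metrics(dist, indep, pairwise)
    assert metrics.er == pytest.approx(1.0, abs=1e-9)
    assert metrics.r_d == pytest.approx(1.0, abs=1e-9)
    assert metrics.r_s == pytest.approx(1.0, abs=1e-9)
    assert metrics.d2 == pytest.approx(0.0, abs=1e-12)


def test_fit_metrics_entropy_hierarchy_and_accuracy():
    """On fitted toy systems: S_N <= S_2 <= S_1, D2 < D1, r_D in (0, 1]."""
    truth = random_model(4, seed=5, scale=1.0)
    series = sample_exact(truth, 20_000, seed=5)
    emp = empirical_distribution(series)
    moments = empirical_moments(series)
    pairwise = fit_pairwise_mem(moments).model
    indep = fit_independent_mem(moments)
    metrics = fit_metrics(emp, indep, pairwise)
    assert metrics.sn <= metrics.s2 + 1e-9 <= metrics.s1 + 1e-9
    assert metrics.d2 < metrics.d1
    assert 0 < metrics.r_d <= 1
    # the product variant differs from the ratio unless r_d = 1 exactly
    prod = fit_metrics(emp, indep, pairwise, er_mode="product")
    assert prod.er == pytest.approx(metrics.r_s * metrics.r_d)


def test_fit_metrics_undefined_ratio():
    indep = SystemModel(n_regions=2, h=np.array([0.3, -0.1]), j=np.zeros((2, 2)))
    dist = boltzmann_distribution(indep)
    with pytest.raises(UndefinedRatioError):
        fit_metrics(dist, indep, indep)  # D1 = 0: already first-order
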