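import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_hybrid_model, random_neq_model
from hbboundary.models import (
    CalibrationError,
    EffectiveConstants,
    PromoterModel,
    RateSet,
    activation_probability,
    build_generator,
    calibrate_boundary,
    compute_tau_bind,
    effective_constants,
    hill_analytic,
    hill_numeric,
    stationary_log_probs,
    steady_state,
    steepness_bound,
)


# -- generators -------------------------------------------------------------


def test_symmetric_two_state_generator(two_state):
    q = build_generator(two_state, 0.0)
    assert np.allclose(q, [[-1.0, 1.0], [1.0, -1.0]])


@pytest.mark.parametrize(
    "model_factory",
    [
        lambda r: PromoterModel(RateSet("eq_chain", r.uniform(0.1, 2, 6), r.uniform(0.1, 2, 6), N=6)),
        random_neq_model,
        random_hybrid_model,
        lambda r: PromoterModel(
            RateSet("two_gradient", r.uniform(0.1, 2, 12), r.uniform(0.1, 2, 12), N=6, L=6)
        ),
        lambda r: PromoterModel(
            RateSet("plus_repressor", r.uniform(0.1, 2, 7), r.uniform(0.1, 2, 7), N=6)
        ),
    ],
    ids=["eq_chain", "neq_graph", "hybrid", "two_gradient", "plus_repressor"],
)
@pytest.mark.parametrize("x", [0.0, 0.8, -1.3])
def test_generator_properties_all_architectures(model_factory, x, rng):
    """Rows sum to zero, off-diagonals nonnegative, stationary vector
    is a probability distribution annihilated by the transposed
    generator."""
    m = model_factory(rng)
    q = build_generator(m, x)
    assert q.shape == (m.n_states, m.n_states)
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-10)
    off = q - np.diag(np.diag(q))
    assert np.all(off >= 0)
    pi = steady_state(q)
    assert np.all(pi >= 0)
    assert math.isclose(pi.sum(), 1.0, rel_tol=1e-12)
    assert np.allclose(pi @ q, 0.0, atol=1e-10)


def test_binding_entries_scale_with_concentration(rng):
    b, u = rng.uniform(0.5, 2, 2), rng.uniform(0.5, 2, 2)
    m = PromoterModel(RateSet("eq_chain", b, u, N=2))
    q0 = build_generator(m, 0.0)
    q1 = build_generator(m, math.log(2.0))
    up = np.triu_indices(3, 1)
    lo = np.tril_indices(3, -1)
    assert np.allclose(q1[up], 2.0 * q0[up])
    assert np.allclose(q1[lo], q0[lo])


def test_state_space_sizes():
    assert PromoterModel(RateSet("eq_chain", [1] * 6, [1] * 6, N=6)).n_states == 7
    assert PromoterModel(RateSet("neq_graph", [1] * 12, [1] * 12, N=3)).n_states == 8
    assert PromoterModel(RateSet("hybrid", [1] * 15, [1] * 15, N=6)).n_states == 11
    assert PromoterModel(RateSet("two_gradient", [1] * 12, [1] * 12, N=6, L=6)).n_states == 49
    assert PromoterModel(RateSet("plus_repressor", [1] * 7, [1] * 7, N=6)).n_states == 14


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        RateSet("eq_chain", [-1.0], [1.0], N=1)
    with pytest.raises(ValueError):
        RateSet("eq_chain", [0.0], [1.0], N=1)  # zero rate: equilibrium chain
    with pytest.raises(ValueError):
        RateSet("no_such_arch", [1.0], [1.0], N=1)
    # zero rates are legal irreversible edges in the occupancy graph
    RateSet("neq_graph", [0.0] * 12, [1.0] * 12, N=3)


# -- steady states ----------------------------------------------------------


def test_two_state_symmetric_steady_state(two_state):
    assert np.allclose(steady_state(build_generator(two_state, 0.0)), [0.5, 0.5])


def test_chain_closed_form_steady_state(chain_n2):
    # K~ = (1, 1, 2) at the boundary: pi proportional to K~
    assert np.allclose(steady_state(build_generator(chain_n2, 0.0)), [0.25, 0.25, 0.5])


@pytest.mark.parametrize("x", [0.0, 0.5, -0.9])
def test_chain_steady_state_matches_ktilde_form(rng, x):
    b, u = rng.uniform(0.1, 3, 6), rng.uniform(0.1, 3, 6)
    m = PromoterModel(RateSet("eq_chain", b, u, N=6))
    kt = effective_constants(m.rates).ktilde
    expected = kt * np.exp(np.arange(7) * x)
    expected /= expected.sum()
    assert np.max(np.abs(steady_state(build_generator(m, x)) - expected)) < 1e-10


def test_chain_detailed_balance(rng):
    b, u = rng.uniform(0.1, 3, 6), rng.uniform(0.1, 3, 6)
    m = PromoterModel(RateSet("eq_chain", b, u, N=6))
    x = 0.37
    pi = steady_state(build_generator(m, x))
    conc = math.exp(x)
    for i in range(6):
        assert math.isclose(pi[i] * b[i] * conc, pi[i + 1] * u[i], rel_tol=1e-9)


@pytest.mark.parametrize("arch_factory", [random_neq_model, random_hybrid_model],
                         ids=["neq_graph", "hybrid"])
def test_tree_steady_state_matches_nullspace(arch_factory, rng):
    """Matrix-tree log-domain stationary distribution vs an independent
    null-space solve of the dense generator."""
    for x in (0.0, 0.6, -1.1):
        m = arch_factory(rng)
        pi_tree = np.exp(stationary_log_probs(m, x))
        pi_null = steady_state(build_generator(m, x))
        assert np.max(np.abs(pi_tree - pi_null)) < 1e-10


def test_degenerate_chain_flagged():
    from hbboundary.models import DegenerateChainError

    # two disconnected components: no unique stationary vector
    q = np.zeros((4, 4))
    q[0, 1] = q[1, 0] = 1.0
    q[2, 3] = q[3, 2] = 1.0
    np.fill_diagonal(q, -q.sum(axis=1))
    with pytest.raises(DegenerateChainError):
        steady_state(q)


# -- activation probability -------------------------------------------------


def test_activation_probability_basics(chain_n2):
    assert math.isclose(activation_probability(chain_n2, 0.0), 0.5, abs_tol=1e-12)
    assert activation_probability(chain_n2, 40.0) > 1 - 1e-6
    assert activation_probability(chain_n2, -40.0) < 1e-6


def test_activation_monotone_for_chain(rng):
    b, u = rng.uniform(0.1, 3, 6), rng.uniform(0.1, 3, 6)
    m = PromoterModel(RateSet("eq_chain", b, u, N=6))
    xs = np.linspace(-5, 5, 101)
    p = activation_probability(m, xs)
    assert np.all(np.diff(p) > 0)


def test_two_gradient_activation_factorizes(rng):
    b, u = rng.uniform(0.1, 3, 12), rng.uniform(0.1, 3, 12)
    m = PromoterModel(RateSet("two_gradient", b, u, N=6, L=6))
    x = 0.4
    act = PromoterModel(RateSet("eq_chain", b[:6], u[:6], N=6))
    rep = PromoterModel(RateSet("eq_chain", b[6:], u[6:], N=6))
    p_act = activation_probability(act, x)
    pi_rep = steady_state(build_generator(rep, -x))
    expected = p_act * pi_rep[0]
    assert math.isclose(activation_probability(m, x), expected, rel_tol=1e-9)


def test_k_or_more_activation(rng):
    b, u = rng.uniform(0.5, 2, 4), rng.uniform(0.5, 2, 4)
    m = PromoterModel(RateSet("eq_chain", b, u, N=4, K=2), activation_rule="k_or_more")
    pi = steady_state(build_generator(m, 0.3))
    assert math.isclose(activation_probability(m, 0.3), pi[2:].sum(), rel_tol=1e-9)


# -- calibration ------------------------------------------------------------


def test_calibrate_noop_when_symmetric(two_state):
    out = calibrate_boundary(two_state)
    assert np.allclose(out.rates.unbinding_rates, two_state.rates.unbinding_rates)
    assert out.boundary_calibrated


def test_unbinding_scale_translates_boundary(rng):
    """Multiplying all unbinding rates by gamma moves the half-max by
    exactly ln(gamma) for the chain (K~_i -> K~_i gamma^{-i})."""
    from hbboundary.models import _find_half_max

    b, u = rng.uniform(0.1, 1.5, 6), rng.uniform(0.1, 5, 6)
    gamma = 3.7
    x1 = _find_half_max(PromoterModel(RateSet("eq_chain", b, u, N=6)))
    x2 = _find_half_max(PromoterModel(RateSet("eq_chain", b, u * gamma, N=6)))
    assert math.isclose(x2 - x1, math.log(gamma), rel_tol=1e-9)


@pytest.mark.parametrize("factory", [random_neq_model, random_hybrid_model],
                         ids=["neq_graph", "hybrid"])
def test_calibration_postcondition_and_idempotence(factory, rng):
    m = calibrate_boundary(factory(rng))
    assert abs(activation_probability(m, 0.0) - 0.5) <= 1e-9
    again = calibrate_boundary(m)
    assert np.allclose(again.rates.unbinding_rates, m.rates.unbinding_rates, rtol=1e-6)


def test_uncalibratable_repressor_rejected():
    # repressor site nearly always bound: activation saturates below 0.5
    rates = RateSet(
        "plus_repressor",
        np.concatenate([np.full(6, 1.0), [100.0]]),
        np.concatenate([np.full(6, 1.0), [1e-6]]),
        N=6,
    )
    with pytest.raises(CalibrationError):
        calibrate_boundary(PromoterModel(rates))


def test_calibration_preserves_binding_caps(rng):
    caps = RateSet("eq_chain", np.full(6, 1e-3), np.ones(6), N=6).binding_caps()
    b = caps * rng.uniform(0.5, 1.0, 6)
    m = calibrate_boundary(PromoterModel(RateSet("eq_chain", b, rng.uniform(0.1, 10, 6), N=6)))
    assert m.rates.check_caps()


# -- Hill coefficients ------------------------------------------------------


def test_hill_single_site_is_one():
    assert hill_analytic(EffectiveConstants.from_ktilde([1.0, 1.0])) == 1.0


def test_hill_maximal_when_intermediates_vanish():
    eps = 1e-12
    kt = EffectiveConstants.from_ktilde([1.0] + [eps] * 5 + [1.0 + 5 * eps])
    assert math.isclose(hill_analytic(kt), 6.0, abs_tol=1e-9)


def test_hill_chain_n2_value(chain_n2):
    kt = effective_constants(chain_n2.rates)
    assert math.isclose(hill_analytic(kt), 1.5, rel_tol=1e-12)
    assert math.isclose(hill_numeric(chain_n2), 1.5, abs_tol=1e-6)


def test_hill_analytic_matches_numeric_randomized(rng):
    for _ in range(20):
        b, u = rng.uniform(0.05, 5, 6), rng.uniform(0.05, 5, 6)
        m = calibrate_boundary(PromoterModel(RateSet("eq_chain", b, u, N=6)))
        ha = hill_analytic(effective_constants(m.rates))
        hn = hill_numeric(m)
        assert abs(ha - hn) < 1e-6
        assert 1 - 1e-6 <= hn <= 6 + 1e-6


def test_hill_requires_calibration(chain_n2, rng):
    m = PromoterModel(RateSet("eq_chain", rng.uniform(1, 2, 3), rng.uniform(1, 2, 3), N=3))
    with pytest.raises(ValueError):
        hill_numeric(m)
    with pytest.raises(ValueError):
        hill_analytic(effective_constants(m.rates))


def test_hill_respects_switching_time_bound(rng):
    """Calibrated chains with capped binding obey
    H <= N - (N-1) tau_bind / tau_active."""
    caps = RateSet("eq_chain", np.full(6, 1e-3), np.ones(6), N=6).binding_caps()
    for _ in range(20):
        b = np.minimum(10 ** rng.uniform(-3, 3, 6), caps)
        u = 10 ** rng.uniform(-3, 3, 6)
        m = calibrate_boundary(PromoterModel(RateSet("eq_chain", b, u, N=6)))
        h = hill_numeric(m)
        bound = steepness_bound(6, m.rates.tau_bind, m.rates.tau_active)
        assert h <= bound + 1e-6


# -- scalar helpers ---------------------------------------------------------


def test_steepness_bound_limits():
    assert steepness_bound(6, 4.0, 1e12) == pytest.approx(6.0)
    assert steepness_bound(6, 4.0, 4.0) == pytest.approx(1.0)
    assert steepness_bound(6, 4.0, 20.0) == pytest.approx(5.0)


def test_tau_bind_default_and_scaling():
    assert compute_tau_bind() == pytest.approx(4.0)
    assert compute_tau_bind(diffusion=2 * 7.4) == pytest.approx(2.0)
    with pytest.raises(ValueError):
        compute_tau_bind(diffusion=-1.0)


# -- serialization ----------------------------------------------------------


def test_json_round_trip(rng):
    m = random_hybrid_model(rng)
    m2 = PromoterModel.from_json(m.to_json())
    assert m2.architecture == "hybrid"
    assert np.allclose(m2.rates.binding_rates, m.rates.binding_rates)
    assert np.allclose(m2.rates.unbinding_rates, m.rates.unbinding_rates)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_generator_rows_sum_zero_property(seed):
    r = np.random.default_rng(seed)
    m = random_neq_model(r, lo=1e-3, hi=1e3)
    q = build_generator(m, float(r.normal()))
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-8 * np.abs(q).max())
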