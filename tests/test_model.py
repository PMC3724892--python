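"""ODE right-hand side, simulation, and their analytic/conservation oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

import flavopath as fp
from flavopath.model import CompiledSystem

from conftest import make_one_state, make_two_state, random_instance


# -- reaction_rate -------------------------------------------------------------


@pytest.mark.parametrize(
    "args,expected",
    [
        ((0.5, 0.8, 10.0), 4.0),
        ((3.0, 0.7, 0.0), 0.0),
        ((0.0, 0.9, 5.0), 0.0),
        ((0.5, 0.8), 0.4),  # influx form: no substrate factor
    ],
)
def test_reaction_rate_product_formula(args, expected):
    assert fp.reaction_rate(*args) == pytest.approx(expected)


@pytest.mark.parametrize("args", [(-1.0, 1.0, 1.0), (1.0, -0.1, 1.0), (1.0, 1.0, -2.0)])
def test_reaction_rate_rejects_negative(args):
    with pytest.raises(fp.DomainError):
        fp.reaction_rate(*args)


# -- rhs -----------------------------------------------------------------------


def test_rhs_zero_rates_zero_derivative(topo, unit_profiles_factory):
    profiles = unit_profiles_factory(topo)
    params = fp.RateParameters.from_array(topo, np.zeros(22))
    state = np.full(12, 3.0)
    out = fp.rhs(6.0, state, params, profiles, topo, tissue="tissue")
    assert np.all(out == 0)


def test_rhs_single_conversion_antisymmetry(unit_profiles_factory):
    topo, params = make_two_state(influx_rate=0.0, conversion_rate=1.0, reduction_rate=0.0)
    profiles = unit_profiles_factory(topo)
    out = fp.rhs(6.0, np.array([2.0, 0.0]), params, profiles, topo, tissue="tissue")
    assert out == pytest.approx([-2.0, 2.0])


def test_rhs_total_mass_rate_equals_influx_minus_reductions(topo):
    """Conversion fluxes cancel in the species sum: d(total)/dt must equal the
    influx flux minus the summed reduction fluxes (direct flux-list oracle)."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        params, profiles, x0 = random_instance(topo, rng)
        t = rng.uniform(5, 9)
        deriv = fp.rhs(t, x0, params, profiles, topo, tissue="t")
        tp = profiles.for_tissue("t")
        expected = 0.0
        for r in topo.reactions:
            lvl = tp.level(r.enzyme, t) if r.enzyme else 1.0
            if r.kind == "influx":
                expected += params[r.id] * lvl
            elif r.kind == "reduction":
                expected -= params[r.id] * x0[topo.species_index(r.source)]
        assert deriv.sum() == pytest.approx(expected, rel=1e-10)


def test_rhs_outside_profile_domain_raises(topo):
    rng = np.random.default_rng(0)
    params, profiles, x0 = random_instance(topo, rng)
    with pytest.raises(fp.DomainError):
        fp.rhs(4.0, x0, params, profiles, topo, tissue="t")


# -- simulate ------------------------------------------------------------------


def test_one_state_matches_closed_form(unit_profiles_factory):
    """Influx r with first-order loss d from zero: x(t) = (r/d)(1 - e^{-d(t-5)})."""
    r, d = 1.0, 0.5
    topo, params = make_one_state(r, d)
    profiles = unit_profiles_factory(topo)
    traj = fp.simulate(topo, params, profiles, np.zeros(1), 5.0, 9.0, tissue="tissue")
    expected = (r / d) * (1 - np.exp(-d * (traj.t - 5.0)))
    assert traj.series("X")[-1] == pytest.approx(1.7293, abs=1e-3)
    assert np.allclose(traj.series("X"), expected, rtol=1e-6, atol=1e-9)


def test_two_state_chain_matches_matrix_exponential(unit_profiles_factory):
    """With constant profiles the system is linear time-invariant; a single
    matrix exponential of the augmented system is the exact solution."""
    topo, params = make_two_state(1.3, 2.0, 0.4)
    profiles = unit_profiles_factory(topo)
    traj = fp.simulate(topo, params, profiles, np.zeros(2), 5.0, 9.0, tissue="tissue")
    A = np.array([[-2.0, 0.0, 1.3], [2.0, -0.4, 0.0], [0.0, 0.0, 0.0]])
    exact = expm(A * 4.0) @ np.array([0.0, 0.0, 1.0])
    assert traj.states[-1] == pytest.approx(exact[:2], rel=1e-6)


def test_zero_rates_constant_trajectory(topo, unit_profiles_factory):
    profiles = unit_profiles_factory(topo)
    params = fp.RateParameters.from_array(topo, np.zeros(22))
    x0 = np.arange(12, dtype=float)
    traj = fp.simulate(topo, params, profiles, x0, 5.0, 9.0, tissue="tissue")
    assert np.allclose(traj.states, x0, atol=1e-12)


def test_superposition_under_zero_influx(topo):
    """Zero-influx system is linear homogeneous: trajectories add pointwise."""
    rng = np.random.default_rng(3)
    params, profiles, _ = random_instance(topo, rng, k_scale=5.0)
    values = params.to_dict()
    for r in topo.reactions:
        if r.kind == "influx":
            values[r.id] = 0.0
    params = fp.RateParameters(values)
    a = rng.uniform(0, 2, 12)
    b = rng.uniform(0, 2, 12)
    settings = fp.SolverSettings(rtol=1e-11, atol=1e-13)
    run = lambda x0: fp.simulate(
        topo, params, profiles, x0, 5.0, 9.0, settings, tissue="t"
    ).states
    assert np.max(np.abs(run(a + b) - (run(a) + run(b)))) < 1e-8


def test_nonnegativity_of_random_simulations(topo):
    rng = np.random.default_rng(5)
    settings = fp.SolverSettings()
    for _ in range(10):
        params, profiles, x0 = random_instance(topo, rng)
        traj = fp.simulate(topo, params, profiles, x0, 5.0, 9.0, settings, tissue="t")
        assert traj.states.min() >= -10 * settings.atol


def test_mass_balance_against_flux_quadrature(topo):
    """Change in total concentration equals integrated influx minus integrated
    reductions (trapezoid quadrature of the rate series)."""
    rng = np.random.default_rng(9)
    fine = fp.SolverSettings(grid_step=0.0025)  # quadrature-limited check
    for _ in range(20):
        params, profiles, x0 = random_instance(topo, rng)
        traj = fp.simulate(topo, params, profiles, x0, 5.0, 9.0, fine, tissue="t")
        sys = CompiledSystem(topo, profiles.for_tissue("t"), params.as_array(topo))
        levels = sys.level_matrix(traj.t)
        net = np.zeros(len(traj.t))
        for i, r in enumerate(topo.reactions):
            if r.kind == "influx":
                net += sys.k[i] * levels[i]
            elif r.kind == "reduction":
                net -= sys.k[i] * traj.series(r.source)
        integral = np.trapezoid(net, traj.t)
        delta = traj.states[-1].sum() - traj.states[0].sum()
        scale = max(abs(delta), abs(integral), 1e-12)
        assert abs(delta - integral) / scale < 1e-4


def test_expm_propagator_matches_stiff_solver(topo):
    rng = np.random.default_rng(13)
    params, profiles, x0 = random_instance(topo, rng, k_scale=10.0)
    strict = fp.simulate(
        topo, params, profiles, x0, 5.0, 9.0,
        fp.SolverSettings(rtol=1e-10, atol=1e-12), tissue="t",
    )
    fast = fp.simulate(
        topo, params, profiles, x0, 5.0, 9.0,
        fp.SolverSettings(method="expm"), tissue="t",
    )
    assert np.allclose(fast.states, strict.states, rtol=1e-2, atol=1e-4)


def test_simulate_window_outside_profiles_raises(topo):
    rng = np.random.default_rng(1)
    params, profiles, x0 = random_instance(topo, rng)
    with pytest.raises(fp.DomainError):
        fp.simulate(topo, params, profiles, x0, 4.0, 9.0, tissue="t")


def test_negative_initial_state_rejected(one_state, unit_profiles_factory):
    topo, params = one_state
    profiles = unit_profiles_factory(topo)
    with pytest.raises(fp.InputError):
        fp.simulate(topo, params, profiles, np.array([-1.0]), 5.0, 9.0, tissue="tissue")


def test_rate_parameters_validation(topo):
    with pytest.raises(fp.InputError):
        fp.RateParameters({"x": -1.0})
    with pytest.raises(fp.InputError):
        fp.RateParameters({"only": 1.0}).as_array(topo)
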