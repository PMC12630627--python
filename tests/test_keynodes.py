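"""Aggregated key-node chain: state probabilities, E[tau_k], hazards."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.optimize import brentq

from signalnet.keynodes import (
    activation_rate_curve,
    expected_hitting_time,
    fit_exponential_rate,
    solve_state_probabilities,
)
from signalnet.meanfield import solve_activation
from signalnet.rates import make_rates


def birth_death_expected_absorption(k, lam, mu):
    """Independent oracle: closed-form first-passage expectation for the
    constant-rate absorbing birth-death chain with up-rates (k-i)lam and
    down-rates i*mu."""
    b = [(k - i) * lam for i in range(k)]
    d = [i * mu for i in range(k + 1)]
    pi = [1.0]
    for i in range(1, k):
        pi.append(pi[-1] * b[i - 1] / d[i])
    return sum(sum(pi[: j + 1]) / (b[j] * pi[j]) for j in range(k))


def literal_k1_oracle(lam, mu):
    """Closed-form solution of the 2x2 literal system for constant rates.

    dp0/dt = mu*p1 - lam*p0, dp1/dt = lam*p0; eigen-decomposition gives
    p1(t) = A(exp(s1 t) - exp(s2 t)); returns (t*, integral of 1-p1 to t*)
    where t* is the first root of p1(t) = 1.
    """
    disc = np.sqrt(lam**2 + 4 * lam * mu)
    s1, s2 = (-lam + disc) / 2, (-lam - disc) / 2
    A = lam / (s1 - s2)

    def p1(t):
        return A * (np.exp(s1 * t) - np.exp(s2 * t))

    t_star = brentq(lambda t: p1(t) - 1.0, 1e-6, 100.0, xtol=1e-12)
    integral = t_star - A * (
        (np.exp(s1 * t_star) - 1) / s1 - (np.exp(s2 * t_star) - 1) / s2
    )
    return t_star, integral


class TestStateProbabilities:
    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_initial_conditions(self, constant_rates, constant_traj, k):
        dist = solve_state_probabilities(constant_rates, k, "literal", constant_traj)
        p0 = dist.evaluate(0.0)
        assert p0[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(p0[1:], 0.0, atol=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 5, 7])
    def test_conservation_k_ge_2(self, constant_rates, constant_traj, k):
        dist = solve_state_probabilities(constant_rates, k, "literal", constant_traj)
        ts = np.linspace(0, dist.t_end, 200)
        total = dist.evaluate(ts).sum(axis=0)
        assert np.max(np.abs(total - 1.0)) <= 1e-6

    @pytest.mark.parametrize("family", ["constant", "exp_decay_const", "log_pair"])
    @pytest.mark.parametrize("k", [2, 4])
    def test_invariants_across_families(self, all_families, family, k):
        rp = all_families[family]
        traj = solve_activation(rp)
        dist = solve_state_probabilities(rp, k, "literal", traj)
        ts = np.linspace(0, dist.t_end, 300)
        p = dist.evaluate(ts)
        assert np.all(p >= -1e-9)
        assert np.max(np.abs(p.sum(axis=0) - 1.0)) <= 1e-6
        assert np.all(np.diff(p[k]) >= -1e-9)  # absorption is monotone

    def test_matches_matrix_exponential_oracle(self, constant_rates, constant_traj):
        # constant rates make the chain time-homogeneous: compare to expm(Qt)
        k, lam, mu = 3, 0.45, 0.65
        Q = np.zeros((k + 1, k + 1))
        for i in range(k):
            Q[i, i + 1] = (k - i) * lam
        for i in range(1, k):  # state k is absorbing: no down-rate out of it
            Q[i, i - 1] = i * mu
        np.fill_diagonal(Q, -Q.sum(axis=1))
        dist = solve_state_probabilities(constant_rates, k, "literal", constant_traj)
        for t in (0.5, 2.0, 7.0):
            expected = expm(Q.T * t) @ np.eye(k + 1)[0]
            np.testing.assert_allclose(dist.evaluate(t), expected, atol=1e-8)

    def test_literal_k1_mass_grows(self, constant_rates, constant_traj):
        dist = solve_state_probabilities(constant_rates, 1, "literal", constant_traj)
        total = dist.evaluate(5.0).sum()
        assert total > 1.0 + 1e-3  # the mu-feedback into p0 leaks mass in

    def test_consistent_k1_conserves(self, constant_rates, constant_traj):
        dist = solve_state_probabilities(constant_rates, 1, "consistent", constant_traj)
        ts = np.linspace(0, dist.t_end, 100)
        assert np.max(np.abs(dist.evaluate(ts).sum(axis=0) - 1.0)) <= 1e-8

    def test_modes_coincide_for_k2(self, constant_rates, constant_traj):
        d1 = solve_state_probabilities(constant_rates, 2, "literal", constant_traj)
        d2 = solve_state_probabilities(constant_rates, 2, "consistent", constant_traj)
        ts = np.linspace(0, 10, 50)
        np.testing.assert_allclose(d1.evaluate(ts), d2.evaluate(ts), atol=1e-10)

    def test_k_validation(self, constant_rates, constant_traj):
        with pytest.raises(ValueError):
            solve_state_probabilities(constant_rates, 0, "literal", constant_traj)


class TestExpectedHittingTime:
    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_constant_rate_birth_death_oracle(self, constant_rates, constant_traj, k):
        dist = solve_state_probabilities(constant_rates, k, "literal", constant_traj)
        got = expected_hitting_time(dist).expectation
        want = birth_death_expected_absorption(k, 0.45, 0.65)
        assert got == pytest.approx(want, rel=1e-4)

    def test_k2_closed_form_value(self, constant_rates, constant_traj):
        # (lam+mu)/(2 lam^2) + 1/lam = 4.9383 for lam=0.45, mu=0.65
        dist = solve_state_probabilities(constant_rates, 2, "literal", constant_traj)
        got = expected_hitting_time(dist).expectation
        assert got == pytest.approx(1.1 / (2 * 0.45**2) + 1 / 0.45, rel=1e-6)

    def test_literal_k1_truncated_at_p1_equals_1(self, constant_rates, constant_traj):
        t_star, integral = literal_k1_oracle(0.45, 0.65)
        assert t_star == pytest.approx(2.77, abs=0.01)
        dist = solve_state_probabilities(constant_rates, 1, "literal", constant_traj)
        res = expected_hitting_time(dist)
        assert res.truncation_time == pytest.approx(t_star, abs=1e-6)
        assert res.expectation == pytest.approx(integral, abs=1e-6)
        assert res.expectation == pytest.approx(1.366, abs=0.002)

    def test_pure_exponential_activation_both_modes(self):
        # mu = 0, lam = c: absorption is a single exponential clock
        rp = make_rates("custom", {"lambda": "0*a + 0.8", "mu": "0*a"})
        traj = solve_activation(rp, t_end=80.0)
        for mode in ("literal", "consistent"):
            dist = solve_state_probabilities(rp, 1, mode, traj)
            got = expected_hitting_time(dist).expectation
            assert got == pytest.approx(1.0 / 0.8, rel=1e-6)

    def test_strictly_increasing_in_k(self, all_families):
        for rp in all_families.values():
            traj = solve_activation(rp)
            vals = []
            for k in range(1, 5):
                dist = solve_state_probabilities(rp, k, "literal", traj)
                vals.append(expected_hitting_time(dist).expectation)
            assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_tail_bound_below_tolerance(self, constant_rates, constant_traj):
        dist = solve_state_probabilities(constant_rates, 3, "literal", constant_traj)
        res = expected_hitting_time(dist, tail_tol=1e-8)
        assert 0 <= res.tail_bound <= 1e-8 / 0.45 * 1.01

    def test_fixed_truncation_lowers_slow_cells(self, constant_rates, constant_traj):
        dist = solve_state_probabilities(constant_rates, 6, "literal", constant_traj)
        full = expected_hitting_time(dist).expectation
        trunc = expected_hitting_time(dist, truncate_at=300.0).expectation
        assert trunc < full
        assert trunc == pytest.approx(65.08, abs=0.01)


class TestActivationRate:
    def test_boundary_values(self, constant_rates, constant_traj):
        d2 = solve_state_probabilities(constant_rates, 2, "literal", constant_traj)
        assert activation_rate_curve(d2).evaluate(0.0) == 0.0
        d1 = solve_state_probabilities(constant_rates, 1, "literal", constant_traj)
        assert activation_rate_curve(d1).evaluate(0.0) == pytest.approx(0.45)

    def test_consistent_k1_hazard_is_lambda(self, constant_rates, constant_traj):
        # with p0 = 1 - p1 exactly, the hazard reduces to lambda(a-hat(t))
        dist = solve_state_probabilities(constant_rates, 1, "consistent", constant_traj)
        curve = activation_rate_curve(dist)
        ts = np.linspace(0, 10, 50)
        np.testing.assert_allclose(curve.evaluate(ts), 0.45, atol=1e-7)

    def test_flagged_nan_when_absorbed(self, constant_rates, constant_traj):
        dist = solve_state_probabilities(
            constant_rates, 2, "literal", constant_traj, t_end=200.0
        )
        assert np.isnan(activation_rate_curve(dist).evaluate(200.0))

    def test_aging_hazard_grows_exponentially(self, aging_rates, aging_traj):
        # mid-life window of the aging chain: hazard follows Gompertz growth
        dist = solve_state_probabilities(aging_rates, 2, "literal", aging_traj)
        curve = activation_rate_curve(dist)
        fit = fit_exponential_rate(curve, (20.0, 70.0), n_samples=100)
        assert fit.beta > 0
        assert fit.r_squared > 0.99


class TestGompertzFit:
    def test_exact_exponential_recovered(self):
        from signalnet.keynodes import ActivationRateCurve

        curve = ActivationRateCurve(
            k=1, mode="literal", _fn=lambda t: 0.001 * np.exp(0.08 * np.asarray(t))
        )
        fit = fit_exponential_rate(curve, (0.0, 50.0), n_samples=100)
        assert fit.alpha == pytest.approx(0.001, rel=1e-10)
        assert fit.beta == pytest.approx(0.08, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_curve_zero_slope(self):
        from signalnet.keynodes import ActivationRateCurve

        curve = ActivationRateCurve(k=1, mode="literal", _fn=lambda t: 0.3 + 0 * np.asarray(t))
        fit = fit_exponential_rate(curve, (0.0, 10.0))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_hazard_rejected(self):
        from signalnet.keynodes import ActivationRateCurve

        curve = ActivationRateCurve(k=1, mode="literal", _fn=lambda t: np.asarray(t) - 5.0)
        with pytest.raises(ValueError):
            fit_exponential_rate(curve, (0.0, 10.0))
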