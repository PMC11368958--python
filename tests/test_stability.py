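"""Eigenvalue classification, Lyapunov decay, and convergence experiments."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from wpmdyn import (
    ParameterSet,
    debris_free_equilibrium,
    local_stability,
    lyapunov,
    lyapunov_decay_closed_form,
    positive_equilibrium,
    psi_submatrix,
    reproduction_number,
    verify_global_convergence,
)

rates = st.floats(min_value=0.05, max_value=5.0, allow_nan=False)
params_strategy = st.builds(
    ParameterSet, lambda_=rates, gamma=rates, beta=rates, mu=rates, alpha=rates,
    theta=rates,
)
positive_coord = st.floats(min_value=0.01, max_value=20.0, allow_nan=False)


class TestLocalStability:
    def test_debris_free_eigenvalues_below_threshold(self, set_a):
        """The Jacobian at E0 block-decouples: one eigenvalue is beta*W0 - alpha,
        the others come from the 2x2 (W, R) block."""
        report = local_stability(debris_free_equilibrium(set_a), set_a)
        assert report.classification == "stable"
        got = sorted(ev.real for ev in report.eigenvalues)
        assert got == pytest.approx([-0.8910, -0.1671, -0.0690], abs=5e-5)
        assert all(abs(ev.imag) < 1e-12 for ev in report.eigenvalues)

    def test_stability_exchange_above_threshold(self, set_b):
        assert local_stability(debris_free_equilibrium(set_b), set_b).classification == "unstable"
        assert local_stability(positive_equilibrium(set_b), set_b).classification == "stable"

    def test_psi_submatrix_signs(self, set_a):
        _, trace, det = psi_submatrix(set_a)
        assert trace == pytest.approx(-(set_a.mu + set_a.theta + set_a.gamma))
        assert det == pytest.approx(set_a.gamma * set_a.theta)
        assert trace < 0 < det

    def test_nonexistent_equilibrium_rejected(self, set_a):
        with pytest.raises(ValueError, match="does not exist"):
            local_stability(positive_equilibrium(set_a), set_a)

    @given(params=params_strategy)
    def test_threshold_dichotomy(self, params):
        """BR < 1 => E0 stable; BR > 1 => E0 unstable and E* stable."""
        br = reproduction_number(params).value
        if abs(br - 1.0) < 1e-3:  # avoid numerically marginal cases
            return
        e0_class = local_stability(debris_free_equilibrium(params), params).classification
        if br < 1.0:
            assert e0_class == "stable"
        else:
            assert e0_class == "unstable"
            assert local_stability(positive_equilibrium(params), params).classification == "stable"


class TestLyapunov:
    def test_zero_at_equilibrium(self, set_d):
        eq = positive_equilibrium(set_d)
        L, dLdt = lyapunov(eq.point, set_d, eq)
        assert L == pytest.approx(0.0, abs=1e-14)
        assert dLdt == pytest.approx(0.0, abs=1e-14)

    def test_closed_form_hand_value(self, set_d):
        """With alpha = gamma, dL/dt depends only on R; at R = 1 it is
        -((mu+theta)*theta + alpha*theta)*(1 - R*)^2 = -1.1638."""
        eq = positive_equilibrium(set_d)
        assert lyapunov_decay_closed_form((5.0, 2.0, 1.0), set_d, eq) == pytest.approx(-1.1638)

    @given(y=st.tuples(positive_coord, positive_coord, positive_coord))
    def test_chain_rule_matches_closed_form_and_is_nonpositive(self, set_d, y):
        eq = positive_equilibrium(set_d)
        _, dLdt = lyapunov(y, set_d, eq)
        closed = lyapunov_decay_closed_form(y, set_d, eq)
        assert abs(dLdt - closed) < 1e-8
        assert dLdt <= 1e-12
        if abs(y[2] - eq.point.R) > 1e-6:
            assert dLdt < 0.0

    @given(params=params_strategy, y=st.tuples(positive_coord, positive_coord, positive_coord))
    def test_chain_rule_matches_closed_form_generally(self, params, y):
        """The two-term closed form holds for any alpha, gamma (cross term included)."""
        eq = positive_equilibrium(params)
        if not eq.exists:
            return
        _, dLdt = lyapunov(y, params, eq)
        closed = lyapunov_decay_closed_form(y, params, eq)
        scale = 1.0 + abs(closed)
        assert abs(dLdt - closed) < 1e-8 * scale

    def test_requires_positive_state_and_positive_equilibrium(self, set_d, set_a):
        eq = positive_equilibrium(set_d)
        with pytest.raises(ValueError, match="positive"):
            lyapunov((0.0, 1.0, 1.0), set_d, eq)
        with pytest.raises(ValueError, match="positive"):
            lyapunov((1.0, 1.0, 1.0), set_a, positive_equilibrium(set_a))


class TestGlobalConvergence:
    def test_small_ensembles_reach_the_selected_equilibrium(self, set_a, set_b):
        for params, label in [(set_a, "debris_free"), (set_b, "positive")]:
            report = verify_global_convergence(params, n_init=5, seed=3, horizon=400.0)
            assert report.target.label == label
            assert report.n_converged == report.n_runs == 5
            assert report.failures == ()

    def test_start_at_target_is_trivially_converged(self, set_a):
        from wpmdyn import integrate
        from wpmdyn.stability import convergence_from_trajectories

        target = debris_free_equilibrium(set_a).point
        traj = integrate(set_a, target, 50.0)
        report = convergence_from_trajectories([traj], set_a, tol=1e-3)
        assert report.n_converged == report.n_runs == 1
        assert report.max_final_distance < 1e-3

    def test_limiting_two_compartment_system_converges_to_debris_free_levels(self, set_a):
        """With M eliminated, the (W, R) subsystem relaxes to (W0, R0)."""
        p = set_a

        def limiting(t, y):
            W, R = y
            return [p.lambda_ - p.gamma * W + p.mu * R,
                    p.gamma * W - (p.mu + p.theta) * R]

        sol = solve_ivp(limiting, (0.0, 500.0), [1.5, 1.0], rtol=1e-10, atol=1e-12)
        e0 = debris_free_equilibrium(p)
        assert sol.y[0, -1] == pytest.approx(e0.point.W, abs=1e-6)
        assert sol.y[1, -1] == pytest.approx(e0.point.R, abs=1e-6)
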