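"""Newton-polynomial weights, the fractal-fractional scheme and its oracles."""

import math

import numpy as np
import pytest

from ffsim import (FFMOrders, IntegrationError, Parameters, SolverConfig,
                   State, Trajectory, ab_normalization, classical_reference,
                   fractional_quadrature_oracle, newton_weights, simulate,
                   step)
from ffsim.model import rhs_array
from ffsim.solver import newton_weights_quadrature

ZERO_PARAMS = Parameters(*([0.0] * 11))


class TestABNormalization:
    @pytest.mark.parametrize("xi,expected", [
        (1.0, 1.0),
        (1e-12, 1.0),                    # xi/Gamma(xi) -> 0 as xi -> 0+
        (0.5, 0.7820947917738781),       # 0.5 + 0.5/sqrt(pi)
    ])
    def test_values(self, xi, expected):
        assert ab_normalization(xi) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("xi", [0.0, -0.2, 1.5, math.nan])
    def test_domain(self, xi):
        with pytest.raises(ValueError):
            ab_normalization(xi)


class TestNewtonWeights:
    def test_integer_order_first_weight_is_dt(self):
        for eta, nu, dt in [(2, 2, 0.1), (9, 4, 0.01), (30, 17, 1.7)]:
            w0, _, _ = newton_weights(eta, nu, 1.0, dt)
            assert w0 == pytest.approx(dt, rel=1e-12)

    def test_newest_interval_half_order(self):
        # eta = nu, xi = 1/2, dt = 1: hand-simplified closed forms
        w = newton_weights(3, 3, 0.5, 1.0)
        assert w == pytest.approx((2.0, 16.0 / 3.0, 17.0 / 1.875), rel=1e-12)

    def test_matches_defining_integrals(self):
        """Closed forms agree with adaptive quadrature of the kernel moments."""
        rng = np.random.default_rng(11)
        for _ in range(60):
            eta = int(rng.integers(2, 50))
            nu = int(rng.integers(2, eta + 1))
            xi = float(rng.uniform(0.05, 1.0))
            dt = float(10 ** rng.uniform(-3, 0.5))
            w = np.array(newton_weights(eta, nu, xi, dt))
            q = np.array(newton_weights_quadrature(eta, nu, xi, dt))
            np.testing.assert_allclose(w, q, rtol=1e-9)

    def test_index_errors(self):
        with pytest.raises(IndexError):
            newton_weights(3, 4, 0.5, 0.1)
        with pytest.raises(IndexError):
            newton_weights(3, 1, 0.5, 0.1)


class TestStep:
    def test_requires_three_history_nodes(self, study_params, study_init):
        cfg = SolverConfig(dt=0.1, t_end=1.0)
        short = Trajectory(np.array([0.0, 0.1]),
                           np.vstack([study_init.as_array()] * 2))
        with pytest.raises(ValueError, match="startup"):
            step(short, study_params, FFMOrders(0.8, 0.5), cfg)

    def test_grid_invariance_of_history(self, study_params, study_init):
        """Recomputing node k from truncated history reproduces it exactly."""
        orders = FFMOrders(0.8, 0.5)
        cfg = SolverConfig(dt=0.1, t_end=2.0)
        traj = simulate(study_params, orders, study_init, cfg)
        for k in (3, 7, 15, 20):
            redone = step(traj.truncated(k), study_params, orders, cfg)
            assert np.array_equal(redone.as_array(), traj.states[k])


class TestSimulate:
    def test_quiescent_system_stays_put(self):
        init = State(1, 2, 3, 4, 5)
        traj = simulate(ZERO_PARAMS, FFMOrders(0.8, 0.5), init,
                        SolverConfig(dt=0.1, t_end=2.0))
        assert np.array_equal(traj.states, np.tile(init.as_array(), (21, 1)))

    def test_literal_scheme_without_ic_term_decays_to_zero(self):
        """Dropping the initial-condition term sends a quiescent system to 0."""
        init = State(1, 2, 3, 4, 5)
        traj = simulate(ZERO_PARAMS, FFMOrders(0.8, 0.5), init,
                        SolverConfig(dt=0.1, t_end=2.0, ic_term=False))
        assert np.all(traj.states[1:] == 0.0)

    def test_scalar_decay_matches_exponential(self):
        """Only the Z decay active, xi=lambda_f=1: Z(1) = exp(-a) to 1e-5."""
        a = 0.04
        p = Parameters.from_dict({**ZERO_PARAMS.as_dict(), "a": a})
        traj = simulate(p, FFMOrders(1.0, 1.0), State(0, 0, 0, 0, 1.0),
                        SolverConfig(dt=0.01, t_end=1.0))
        assert traj.states[-1, 4] == pytest.approx(math.exp(-a), rel=1e-5)

    def test_classical_limit_matches_adaptive_oracle(self, study_params, study_init):
        cfg = SolverConfig(dt=0.01, t_end=5.0)
        traj = simulate(study_params, FFMOrders(1.0, 1.0), study_init, cfg)
        ref = classical_reference(study_params, study_init, cfg)
        err = (np.max(np.abs(traj.states - ref.states), axis=0)
               / np.max(np.abs(ref.states), axis=0))
        assert np.all(err < 1e-3)

    @pytest.mark.parametrize("orders", [FFMOrders(1.0, 1.0), FFMOrders(0.7, 0.5),
                                        FFMOrders(0.9, 0.2)])
    def test_first_step_signs_follow_initial_rates(self, study_params, study_init,
                                                   orders):
        """T, C, IL2, Z decrease and D increases from the study initial state."""
        traj = simulate(study_params, orders, study_init,
                        SolverConfig(dt=0.01, t_end=1.0))
        # for lambda_f < 1 node 1 equals node 0 exactly (the origin carries no
        # fractal weight), so the first moving node is node 2
        k = 1 if orders.lambda_f == 1.0 else 2
        increments = traj.states[k] - traj.states[0]
        signs = np.sign(rhs_array(study_init.as_array(), study_params))
        np.testing.assert_array_equal(np.sign(increments), signs)

    def test_self_convergence_under_refinement(self, study_params, study_init):
        """Cauchy differences shrink under dt halving (measured for t >= 1,
        past the initial layer where the t**(lambda_f-1) local term is
        singular for lambda_f < 1)."""
        orders = FFMOrders(0.7, 0.5)
        trajs = [simulate(study_params, orders, study_init,
                          SolverConfig(dt=dt, t_end=5.0))
                 for dt in (0.04, 0.02, 0.01)]
        i0 = 25  # t = 1 on the coarsest grid
        e1 = np.max(np.abs(trajs[0].states[i0:] - trajs[1].states[::2][i0:]))
        e2 = np.max(np.abs(trajs[1].states[::2][i0:] - trajs[2].states[::4][i0:]))
        assert e2 < e1

    def test_deterministic_bit_identical(self, study_params, study_init):
        cfg = SolverConfig(dt=0.05, t_end=2.0)
        a = simulate(study_params, FFMOrders(0.8, 0.5), study_init, cfg)
        b = simulate(study_params, FFMOrders(0.8, 0.5), study_init, cfg)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.rhs_values, b.rhs_values)

    def test_blowup_raises_naming_step(self):
        p = Parameters.from_dict({**ZERO_PARAMS.as_dict(), "alpha": 500.0})
        with pytest.raises(IntegrationError, match="step"):
            simulate(p, FFMOrders(1.0, 1.0), State(1, 0, 0, 0, 0),
                     SolverConfig(dt=1.0, t_end=300.0))

    def test_order_validation(self):
        with pytest.raises(ValueError):
            FFMOrders(xi=0.0, lambda_f=0.5)
        with pytest.raises(ValueError):
            FFMOrders(xi=0.5, lambda_f=1.2)
        with pytest.raises(ValueError):
            SolverConfig(dt=1.0, t_end=2.0)  # fewer than three nodes


class TestClassicalReference:
    def test_dendritic_cells_approach_source_decay_balance(self, study_params,
                                                           study_init):
        """D rises from 0.3 toward mu/(omega+lambda_il2) ~ 2000, monotonically."""
        ref = classical_reference(study_params, study_init,
                                  SolverConfig(dt=0.05, t_end=50.0))
        D = ref.states[:, 2]
        assert np.all(np.diff(D) > 0)
        limit = study_params.mu / (study_params.omega + study_params.lambda_il2)
        assert D[-1] == pytest.approx(limit, rel=1e-4)

    def test_zero_field_constant(self):
        init = State(1, 2, 3, 4, 5)
        ref = classical_reference(ZERO_PARAMS, init, SolverConfig(dt=0.1, t_end=1.0))
        np.testing.assert_allclose(ref.states, np.tile(init.as_array(), (11, 1)),
                                   rtol=1e-12, atol=1e-12)

    def test_tolerance_sweep_self_consistency(self, study_params, study_init):
        cfg = SolverConfig(dt=0.5, t_end=50.0)
        loose = classical_reference(study_params, study_init, cfg, rtol=1e-7,
                                    atol=1e-9)
        tight = classical_reference(study_params, study_init, cfg, rtol=1e-10,
                                    atol=1e-12)
        rel = np.abs(loose.states[-1] - tight.states[-1]) / np.abs(tight.states[-1])
        assert np.all(rel < 1e-6)


class TestFractionalQuadratureOracle:
    def test_integer_limit_matches_classical(self, study_params, study_init):
        cfg = SolverConfig(dt=0.01, t_end=5.0)
        orc = fractional_quadrature_oracle(study_params, FFMOrders(1.0, 1.0),
                                           study_init, cfg)
        ref = classical_reference(study_params, study_init, cfg)
        err = (np.max(np.abs(orc.states - ref.states), axis=0)
               / np.max(np.abs(ref.states), axis=0))
        assert np.all(err < 1e-3)  # trapezoid-type accuracy, O(dt^2)

    def test_cross_checks_scheme_on_scalar_decay(self):
        p = Parameters.from_dict({**ZERO_PARAMS.as_dict(), "a": 0.7})
        orders = FFMOrders(0.8, 0.5)
        cfg = SolverConfig(dt=0.005, t_end=1.0)
        init = State(0, 0, 0, 0, 1.0)
        sim = simulate(p, orders, init, cfg)
        orc = fractional_quadrature_oracle(p, orders, init, cfg)
        # compared past the initial layer (t >= 0.05), where the singular
        # t**(lambda_f-1) local term no longer dominates both discretizations
        i0 = 10
        rel = (np.max(np.abs(sim.states[i0:, 4] - orc.states[i0:, 4]))
               / np.max(np.abs(orc.states[:, 4])))
        assert rel < 0.05

    def test_zero_field_constant(self):
        init = State(1, 2, 3, 4, 5)
        orc = fractional_quadrature_oracle(ZERO_PARAMS, FFMOrders(0.6, 0.4), init,
                                           SolverConfig(dt=0.1, t_end=2.0))
        assert np.array_equal(orc.states, np.tile(init.as_array(), (21, 1)))

    def test_node_limit(self, study_params, study_init):
        with pytest.raises(ValueError, match="2000"):
            fractional_quadrature_oracle(study_params, FFMOrders(0.8, 0.5),
                                         study_init,
                                         SolverConfig(dt=0.01, t_end=50.0))


class TestTrajectory:
    def test_rejects_nonuniform_grid(self):
        with pytest.raises(ValueError, match="uniform"):
            Trajectory(np.array([0.0, 0.1, 0.3]), np.zeros((3, 5)))

    def test_rejects_decreasing_times(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.2, 0.1]), np.zeros((3, 5)))

    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.1]), np.zeros((3, 5)))
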