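import math
from dataclasses import replace

import numpy as np
import pytest

from memnet import build_parameters, derive_constants
from memnet.network import (Phase, StimulusProtocol, build_layout, init_state,
                            ou_step, total_drive, activity_derivative,
                            exc_weight_derivative, inh_weight_derivative,
                            step, population_averages, equilibrium_reached,
                            simulate, NetworkState)


class TestLayout:
    def test_default_block_sizes(self, default_params):
        lay = build_layout(default_params)
        assert lay.pop1.size == lay.pop2.size == 10
        assert lay.background.size == 80
        assert not np.intersect1d(lay.pop1, lay.pop2).size

    def test_tiny_and_boundary_layouts(self):
        lay = build_layout(build_parameters({"n": 4, "n_P": 1}))
        assert lay.background.tolist() == [2, 3]
        lay = build_layout(build_parameters({"n": 2, "n_P": 1}))
        assert lay.background.size == 0


class TestInitState:
    def test_deterministic_given_seed(self, default_params):
        lay = build_layout(default_params)
        a = init_state(default_params, lay, np.random.default_rng(5))
        b = init_state(default_params, lay, np.random.default_rng(5))
        assert np.array_equal(a.W, b.W) and np.array_equal(a.F, b.F)

    def test_weights_distributed_around_balance(self, default_params, rng):
        lay = build_layout(default_params)
        st = init_state(default_params, lay, rng)
        assert st.W.mean() == pytest.approx(default_params.theta, abs=0.01)
        assert np.all(st.W >= 0)
        assert st.F.mean() == pytest.approx(0.07, abs=0.005)

    def test_zero_spread_gives_exact_balance(self, default_params, rng):
        lay = build_layout(default_params)
        st = init_state(default_params, lay, rng, weight_sd=0.0, rate_sd=0.0)
        assert np.all(st.W == default_params.theta)
        assert np.all(st.F == 0.07)


class TestOU:
    def test_target_is_fixed_point_of_drift(self, default_params, rng):
        p = replace(default_params, ou_sigma=0.0)
        F = np.full((2, 10), 0.9)
        out = ou_step(F, (0.9, 0.9), p, rng)
        assert np.allclose(out, 0.9)

    def test_pure_drift_monotone_approach(self, default_params, rng):
        p = replace(default_params, ou_sigma=0.0)
        F = np.zeros((2, 10))
        prev = 0.0
        for _ in range(200):
            F = ou_step(F, (0.9, 0.9), p, rng)
            assert F[0, 0] > prev
            prev = F[0, 0]
        assert prev < 0.9

    def test_stationary_mean_matches_target(self, default_params):
        rng = np.random.default_rng(7)
        F = np.full((2, 500), 0.6)
        samples = []
        for k in range(4000):
            F = ou_step(F, (0.6, 0.3), default_params, rng)
            if k > 500:
                samples.append(F.mean(axis=1))
        m = np.mean(samples, axis=0)
        # stationary sd of each process ~ sigma/sqrt(2 delta); SE over pool
        assert m[0] == pytest.approx(0.6, abs=3 * 0.06 / math.sqrt(500))
        assert m[1] == pytest.approx(0.3, abs=3 * 0.06 / math.sqrt(500))


class TestDerivatives:
    def test_drive_zero_for_silent_network(self, small_params, small_state):
        lay, st = small_state
        st.F[:] = 0.0
        g = total_drive(st, small_params, derive_constants(small_params))
        assert np.allclose(g, 0.0)

    def test_drive_of_single_saturated_synapse(self):
        # one presynaptic neuron at rate 1 through a maximal synapse against
        # baseline inhibition: g = K (1 - theta) = beta * u_max
        p = build_parameters({"n": 2, "n_P": 1})
        c = derive_constants(p)
        st = NetworkState(t=0.0, F=np.array([0.0, 1.0]),
                          W=np.array([[0.0, 1.0], [0.0, 0.0]]),
                          W_inh=np.full((2, 2), p.theta) * np.array([[0, 1], [0, 0]]),
                          F_ex=np.zeros((2, 1)))
        g = total_drive(st, p, c)
        assert g[0] == pytest.approx(c.K * (1 - p.theta))
        assert g[0] == pytest.approx(p.beta * c.u_max)
        assert g[0] == pytest.approx(0.16579, abs=1e-5)

    def test_balanced_weights_cancel(self, small_params, small_state):
        lay, st = small_state
        st.W[:] = small_params.theta
        st.W_inh[:] = small_params.theta
        g = total_drive(st, small_params, derive_constants(small_params))
        assert np.allclose(g, 0.0)

    def test_activity_fixed_point_of_sigmoid_inversion(self, default_params):
        # with zero drive and n_eps = 12 the rate settles where
        # ln(1/F - 1) = K n_eps (1 - theta), i.e. F = 1/(1 + e^(6K)) = 0.1200
        c = derive_constants(default_params)
        F_star = 1.0 / (1.0 + math.exp(c.K * 6.0))
        assert F_star == pytest.approx(0.1200, abs=5e-4)
        d = activity_derivative(np.array([F_star]), np.array([0.0]), default_params, c)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_activity_derivative_vanishes_at_rate_bounds(self, default_params):
        c = derive_constants(default_params)
        d = activity_derivative(np.array([1e-12, 1 - 1e-12]),
                                np.array([0.0, 0.0]), default_params, c)
        assert np.allclose(d, 0.0, atol=1e-9)

    def test_weight_derivative_zero_at_saturation(self, default_params):
        # F_i = F_j = 1, w = 1: 1 + (0.05 - 1)/0.95 = 0
        c = derive_constants(default_params)
        F = np.array([1.0, 1.0])
        dW = exc_weight_derivative(F, np.ones((2, 2)), default_params, c)
        assert np.allclose(dW, 0.0, atol=1e-15)

    def test_weight_derivative_positive_at_zero_weight(self, default_params):
        c = derive_constants(default_params)
        F = np.array([0.3, 0.4])
        dW = exc_weight_derivative(F, np.zeros((2, 2)), default_params, c)
        assert np.all(dW > 0)

    def test_clamped_rate_weight_equilibrium_by_integration(self, default_params):
        # integrate at fixed rates 0.1/0.1: converges to sqrt(0.19) = 0.43589
        c = derive_constants(default_params)
        F = np.array([0.1, 0.1])
        W = np.full((2, 2), 0.5)
        for _ in range(20_000):
            W += 1.0 * exc_weight_derivative(F, W, default_params, c)
        assert W[0, 0] == pytest.approx(math.sqrt(0.19), rel=1e-4)


class TestInhibitoryRule:
    @pytest.fixture
    def inh_params(self):
        return build_parameters({"enabled": True})

    def test_rate_gated_silence(self, inh_params):
        c = derive_constants(inh_params)
        dW = inh_weight_derivative(np.zeros(2), np.full((2, 2), 0.5), inh_params, c)
        assert np.allclose(dW, 0.0)

    def test_down_state_is_absorbing_for_correlated_pairs(self, inh_params):
        # both neurons highly active and similar: down branch, already at theta_d
        c = derive_constants(inh_params)
        F = np.array([0.8, 0.8])
        dW = inh_weight_derivative(F, np.full((2, 2), 0.5), inh_params, c)
        assert np.allclose(dW, 0.0)

    def test_uncorrelated_pair_drifts_to_up_state(self, inh_params):
        c = derive_constants(inh_params)
        F = np.array([0.9, 0.75])   # rate difference 0.15 > delta_F
        dW = inh_weight_derivative(F, np.full((2, 2), 0.5), inh_params, c)
        assert dW[0, 1] == pytest.approx(0.675 * 0.3 / c.tau_w)

    def test_gate_boundaries_are_inactive(self, inh_params):
        # exact equality of the sum gate activates neither branch
        c = derive_constants(inh_params)
        F = np.array([0.1, 0.1])  # sum exactly theta_F = 0.2, diff 0
        dW = inh_weight_derivative(F, np.full((2, 2), 0.6), inh_params, c)
        assert np.all(dW == 0.0)

    def test_weights_stay_inside_attracting_band(self, inh_params, rng):
        c = derive_constants(inh_params)
        W = rng.uniform(0.5, 0.8, size=(4, 4))
        for _ in range(3000):
            F = rng.uniform(0.0, 1.0, size=4)
            W += 0.5 * inh_weight_derivative(F, W, inh_params, c)
        assert np.all(W >= 0.5 - 1e-9) and np.all(W <= 0.8 + 1e-9)


class TestStep:
    def test_euler_convergence_under_step_halving(self):
        p1 = build_parameters({"n": 3, "n_P": 1, "ou_sigma": 0.0, "dt": 1e-3})
        p2 = replace(p1, dt=5e-4)
        phase = Phase(duration=1.0, mode="noise", noise_mean=0.2, noise_sd=0.0)
        ends = []
        for p, steps in ((p1, 1000), (p2, 2000)):
            lay = build_layout(p)
            st = init_state(p, lay, np.random.default_rng(3),
                            weight_sd=0.0, rate_sd=0.0)
            c = derive_constants(p)
            rng = np.random.default_rng(0)
            for _ in range(steps):
                st = step(st, phase, p, c, lay, rng)
            ends.append((st.F.copy(), st.W.copy()))
        # O(dt) global error: halving dt changes the endpoint by O(dt)
        assert np.max(np.abs(ends[0][0] - ends[1][0])) < 5e-3
        assert np.max(np.abs(ends[0][1] - ends[1][1])) < 5e-3

    def test_state_invariants_preserved(self, small_params, small_state, rng):
        lay, st = small_state
        c = derive_constants(small_params)
        phase = Phase(duration=1.0, mode="noise", noise_mean=0.25, noise_sd=0.025)
        for _ in range(200):
            st = step(st, phase, small_params, c, lay, rng)
        assert np.all((st.F > 0) & (st.F < 1))
        assert np.all(st.W >= 0)

    def test_kernel_matches_reference_step_path(self):
        # deterministic protocol (zero noise spread, zero OU diffusion):
        # the compiled chunked integrator and the numpy step() produce the
        # same trajectory
        p = build_parameters({"n": 12, "n_P": 3, "n_Pex": 3,
                              "ou_sigma": 0.0, "enabled": True})
        proto = StimulusProtocol(phases=(
            Phase(duration=0.5, mode="noise", noise_mean=0.25, noise_sd=0.0),
            Phase(duration=0.5, mode="ou", noise_mean=0.25, noise_sd=0.0,
                  ou_means=(0.9, 0.75)),
        ))
        fast = simulate(proto, p, seed=11, sample_every=0.1, use_kernel=True)
        slow = simulate(proto, p, seed=11, sample_every=0.1, use_kernel=False)
        assert np.allclose(fast.final_state.F, slow.final_state.F, atol=1e-12)
        assert np.allclose(fast.final_state.W, slow.final_state.W, atol=1e-12)
        assert np.allclose(fast.final_state.W_inh, slow.final_state.W_inh, atol=1e-12)


class TestAverages:
    def test_uniform_weights_give_uniform_class_means(self, default_params, rng):
        lay = build_layout(default_params)
        st = init_state(default_params, lay, rng)
        st.W[:] = 0.37
        avg = population_averages(st, lay)
        for v in (avg.w11, avg.w22, avg.w21, avg.w12, avg.w1B, avg.w2B):
            assert v == pytest.approx(0.37)

    def test_block_constants_recovered(self, default_params, rng):
        lay = build_layout(default_params)
        st = init_state(default_params, lay, rng)
        st.W[np.ix_(lay.pop1, lay.pop1)] = 0.9
        st.W[np.ix_(lay.pop2, lay.pop1)] = 0.7
        avg = population_averages(st, lay)
        assert avg.w11 == pytest.approx(0.9)
        assert avg.w21 == pytest.approx(0.7)

    def test_class_means_bounded_by_entries(self, default_params, rng):
        lay = build_layout(default_params)
        st = init_state(default_params, lay, rng)
        avg = population_averages(st, lay)
        block = st.W[np.ix_(lay.pop1, lay.pop1)]
        assert block.min() <= avg.w11 <= block.max()


class TestEquilibriumDetection:
    def test_constant_window_is_converged(self):
        t = np.arange(0, 200.0, 1.0)
        w = np.full((t.size, 3), 0.6)
        assert equilibrium_reached(t, w, window=100.0, tol=1e-5)

    def test_linear_drift_is_not_converged(self):
        t = np.arange(0, 200.0, 1.0)
        w = np.outer(t, [1e-3]) + 0.5
        assert not equilibrium_reached(t, w, window=100.0, tol=1e-5)

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            equilibrium_reached(np.array([]), np.zeros((0, 2)))

    def test_short_span_not_yet_converged(self):
        t = np.arange(0, 50.0, 1.0)
        w = np.full((t.size, 2), 0.6)
        assert not equilibrium_reached(t, w, window=100.0)


class TestSimulate:
    def test_tuning_only_protocol(self, small_params):
        proto = StimulusProtocol(phases=(
            Phase(duration=2.0, mode="noise", noise_mean=0.25, noise_sd=0.025),
            Phase(duration=0.0, mode="ou", ou_means=(0.9, 0.75)),
        ))
        traj = simulate(proto, small_params, seed=2, sample_every=0.5)
        assert traj.final_state.t == pytest.approx(2.0)

    def test_reproducible_given_seed(self, small_params):
        proto = StimulusProtocol(phases=(
            Phase(duration=1.0, mode="noise", noise_mean=0.25, noise_sd=0.025),))
        a = simulate(proto, small_params, seed=9, sample_every=0.25)
        b = simulate(proto, small_params, seed=9, sample_every=0.25)
        assert a.table.equals(b.table)
        assert np.array_equal(a.final_state.W, b.final_state.W)
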