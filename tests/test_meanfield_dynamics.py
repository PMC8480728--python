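"""Cross-correlations, drift terms, and the Euler-integrated mean field."""

import numpy as np
import pytest
from scipy.integrate import quad

from whiskstdp import (
    STDPRule,
    ThalamicModel,
    VonMisesSpec,
    WeightProfile,
    cross_corr_pre_post,
    cross_corr_pre_pre,
    default_initial_weights,
    drift_terms,
    euler_integrate,
    hz_to_angular,
    kernel_value,
    make_thalamic_model,
    meanfield_rhs,
    order_parameters,
    uniform_weight,
)


def small_model(N=8, gamma=1.0, seed=5):
    rng = np.random.default_rng(seed)
    return ThalamicModel(
        N=N, D=10.0, gamma=gamma, nu=hz_to_angular(7.0), d=0.003,
        phases=rng.uniform(-np.pi, np.pi, size=N),
    )


def asym_rule(mu=0.01, alpha=1.1, lam=0.01):
    return STDPRule("asymmetric_exponential", 0.022, 0.050, mu, alpha, lam)


class TestCrossCorrelations:
    def test_unmodulated_pair_is_flat(self):
        m = small_model(gamma=0.0)
        smooth, atom = cross_corr_pre_pre(m, 1, 2, dt=0.123)
        assert smooth == pytest.approx(100.0)
        assert atom == 0.0

    def test_same_phase_zero_lag_peak(self):
        m = ThalamicModel(N=2, D=10.0, gamma=1.0, nu=44.0, d=0.0,
                          phases=np.array([0.4, 0.4]))
        smooth, atom = cross_corr_pre_pre(m, 1, 2, dt=0.0)
        assert smooth == pytest.approx(150.0)  # D^2 * (1 + gamma^2/2)
        assert atom == 0.0

    def test_self_correlation_carries_poisson_atom(self):
        m = small_model()
        _, atom = cross_corr_pre_pre(m, 3, 3, dt=0.0)
        assert atom == pytest.approx(m.D)

    def test_pre_post_uniform_weights_flat(self):
        # uniform weights on a balanced (quantile-placed uniform) phase set
        # have no first circular moment: the correlation is lag-independent
        from whiskstdp import place_phases_quantile

        phases = place_phases_quantile(VonMisesSpec(0.0), 16)
        m = ThalamicModel(N=16, D=10.0, gamma=1.0, nu=44.0, d=0.003,
                          phases=phases)
        w = WeightProfile(np.full(16, 0.5))
        op = order_parameters(w, m.phases)
        for dt in (-0.2, 0.0, 0.31):
            smooth, _ = cross_corr_pre_post(1, w, op, m, dt=dt)
            assert smooth == pytest.approx(m.D**2 * 0.5, abs=1e-9)

    def test_pre_post_equals_weighted_sum_of_pre_pre(self):
        # the pooled-neuron correlation is the weight-averaged (delayed)
        # upstream correlation: brute-force summation oracle at small N
        rng = np.random.default_rng(2)
        m = small_model(N=6, seed=9)
        w = WeightProfile(rng.uniform(0.1, 0.9, size=6))
        op = order_parameters(w, m.phases)
        for j in (1, 4):
            for dt in (-0.05, 0.0, 0.02, 0.2):
                brute = np.mean([
                    w.weights[k - 1]
                    * cross_corr_pre_pre(m, j, k, dt - m.d)[0]
                    for k in range(1, 7)
                ])
                smooth, atom = cross_corr_pre_post(j, w, op, m, dt)
                assert smooth == pytest.approx(brute, rel=1e-9)
                assert atom == pytest.approx(w.weights[j - 1] * m.D / m.N)

    def test_pre_post_sum_oracle_on_two_harmonics_free_case(self):
        # with only one synapse the estimator is exact
        m = ThalamicModel(N=1, D=10.0, gamma=0.8, nu=30.0, d=0.004,
                          phases=np.array([0.3]))
        w = WeightProfile(np.array([0.6]))
        op = order_parameters(w, m.phases)
        for dt in (-0.1, 0.0, 0.07):
            brute = 0.6 * cross_corr_pre_pre(m, 1, 1, dt - m.d)[0]
            smooth, _ = cross_corr_pre_post(1, w, op, m, dt)
            assert smooth == pytest.approx(brute, rel=1e-9)


class TestDriftTerms:
    def test_balance_point_zeroes_mean_term(self):
        rule = asym_rule(mu=0.3)
        m = small_model()
        w_star = uniform_weight(rule)
        profile = WeightProfile(np.full(m.N, w_star))
        op = order_parameters(profile, m.phases)
        terms = drift_terms(profile, m.phases, op, rule, m)
        np.testing.assert_allclose(terms.F_0, 0.0, atol=1e-9)

    def test_causal_kernel_makes_self_term_potentiating(self):
        rule = asym_rule()
        m = small_model()
        profile = WeightProfile(np.linspace(0.1, 0.9, m.N))
        op = order_parameters(profile, m.phases)
        terms = drift_terms(profile, m.phases, op, rule, m)
        assert float(kernel_value(rule, "-", m.d)) == 0.0
        assert np.all(terms.F_d >= 0.0)

    def test_rhs_matches_correlation_quadrature_oracle(self):
        # independent oracle: integrate the smooth pre/post correlation
        # against each kernel branch by quadrature, add the delta atom at
        # the delay, and weight with f+/f-
        rng = np.random.default_rng(8)
        m = small_model(N=8, seed=21)
        rule = asym_rule(mu=0.2)
        w = WeightProfile(rng.uniform(0.2, 0.8, size=8))
        op = order_parameters(w, m.phases)
        from whiskstdp import f_minus, f_plus

        expected = np.empty(8)
        for j in range(1, 9):
            span = 0.8
            smooth_p = quad(
                lambda u: cross_corr_pre_post(j, w, op, m, u)[0]
                * kernel_value(rule, "+", u),
                -span, span, limit=800,
            )[0]
            smooth_m = quad(
                lambda u: cross_corr_pre_post(j, w, op, m, u)[0]
                * kernel_value(rule, "-", u),
                -span, span, limit=800,
            )[0]
            atom = w.weights[j - 1] * m.D / m.N
            ip = smooth_p + atom * kernel_value(rule, "+", m.d)
            im = smooth_m + atom * kernel_value(rule, "-", m.d)
            wj = w.weights[j - 1]
            expected[j - 1] = (
                f_plus(wj, rule.mu) * ip - f_minus(wj, rule.mu, rule.alpha) * im
            )
        got = meanfield_rhs(w, m.phases, rule, m)
        np.testing.assert_allclose(got, expected, atol=1e-6 * np.max(np.abs(expected)))

    def test_symmetric_inputs_give_identical_rhs(self):
        from whiskstdp import place_phases_quantile

        phases = place_phases_quantile(VonMisesSpec(0.0), 32)
        m = ThalamicModel(N=32, D=10.0, gamma=1.0, nu=44.0, d=0.003, phases=phases)
        w = WeightProfile(np.full(32, 0.5))
        rhs = meanfield_rhs(w, m.phases, asym_rule(), m)
        np.testing.assert_allclose(rhs, rhs[0], atol=1e-12)

    def test_rate_scaling_homogeneity(self):
        # doubling D quadruples the population drift terms (self term excluded)
        rng = np.random.default_rng(4)
        phases = rng.uniform(-np.pi, np.pi, 12)
        w = WeightProfile(rng.uniform(0.2, 0.8, 12))
        rule = asym_rule()
        m1 = ThalamicModel(N=12, D=10.0, gamma=1.0, nu=44.0, d=0.003, phases=phases)
        m2 = ThalamicModel(N=12, D=20.0, gamma=1.0, nu=44.0, d=0.003, phases=phases)
        r1 = meanfield_rhs(w, phases, rule, m1, include_self_term=False)
        r2 = meanfield_rhs(w, phases, rule, m2, include_self_term=False)
        np.testing.assert_allclose(r2, 4.0 * r1, rtol=1e-12)


class TestEulerIntegration:
    def test_weights_stay_in_bounds(self, headline_trajectory):
        assert np.all(headline_trajectory.weights_final >= 0.0)
        assert np.all(headline_trajectory.weights_final <= 1.0)
        assert np.all(headline_trajectory.w_bar >= 0.0)
        assert np.all(headline_trajectory.w_tilde <= headline_trajectory.w_bar + 1e-12)

    def test_times_strictly_increasing(self, headline_trajectory):
        assert np.all(np.diff(headline_trajectory.times) > 0)

    def test_potentiation_dominated_saturation(self):
        # weak depression at high frequency: all synapses saturate high
        spec = VonMisesSpec(1.0, 0.5)
        m = make_thalamic_model(N=40, D=10.0, gamma=1.0, nu=hz_to_angular(200.0),
                                d=0.003, phase_spec=spec)
        rule = asym_rule(alpha=0.9)
        traj = euler_integrate(default_initial_weights(40, seed=1), rule, m,
                               n_steps=40_000, dt=0.1, record_every=1000)
        assert traj.weights_final.min() > 0.9

    def test_depression_dominated_collapse(self):
        spec = VonMisesSpec(1.0, 0.5)
        m = make_thalamic_model(N=40, D=10.0, gamma=1.0, nu=hz_to_angular(7.0),
                                d=0.003, phase_spec=spec)
        rule = asym_rule(alpha=3.0)
        traj = euler_integrate(default_initial_weights(40, seed=1), rule, m,
                               n_steps=60_000, dt=0.1, record_every=1000)
        assert traj.w_bar[-1] < 0.05

    def test_high_frequency_uniform_convergence(self):
        spec = VonMisesSpec(1.0, 5 * np.pi / 6)
        m = make_thalamic_model(N=60, D=10.0, gamma=1.0, nu=hz_to_angular(200.0),
                                d=0.003, phase_spec=spec)
        rule = STDPRule("symmetric_gaussian", 0.022, 0.050, 0.01, 1.1, 0.01)
        traj = euler_integrate(default_initial_weights(60, seed=0), rule, m,
                               n_steps=50_000, dt=0.1, record_every=5000,
                               include_self_term=False)
        w_star = uniform_weight(rule)
        assert np.max(np.abs(traj.weights_final - w_star)) < 1e-3

    def test_step_size_robustness(self):
        spec = VonMisesSpec(1.0, 0.5)
        m = make_thalamic_model(N=30, D=10.0, gamma=0.9, nu=hz_to_angular(7.0),
                                d=0.003, phase_spec=spec)
        rule = asym_rule(mu=0.1)
        init = default_initial_weights(30, seed=2)
        a = euler_integrate(init, rule, m, n_steps=20_000, dt=0.1, record_every=20_000)
        b = euler_integrate(init, rule, m, n_steps=40_000, dt=0.05, record_every=40_000)
        assert a.w_bar[-1] == pytest.approx(b.w_bar[-1], abs=1e-3)
        assert a.w_tilde[-1] == pytest.approx(b.w_tilde[-1], abs=1e-3)

    def test_time_rescaling_leaves_path_invariant(self):
        spec = VonMisesSpec(1.0, 0.5)
        m = make_thalamic_model(N=20, D=10.0, gamma=1.0, nu=hz_to_angular(7.0),
                                d=0.003, phase_spec=spec)
        init = default_initial_weights(20, seed=3)
        a = euler_integrate(init, asym_rule(lam=0.01), m, n_steps=5000, dt=0.1)
        b = euler_integrate(init, asym_rule(lam=0.1), m, n_steps=5000, dt=0.01)
        np.testing.assert_allclose(a.w_bar, b.w_bar, atol=1e-12)
        np.testing.assert_allclose(a.times, b.times, atol=1e-12)

    def test_limit_cycle_recurrence(self, headline_trajectory):
        # post-transient order parameters recur while the phase wraps:
        # the dynamics live on a limit cycle, not a fixed point
        wb = headline_trajectory.w_bar
        wt = headline_trajectory.w_tilde
        half = len(wb) // 2
        state = np.column_stack([wb[half:], wt[half:]])
        ref = state[0]
        dist = np.linalg.norm(state - ref, axis=1)
        # find a later close return after having moved away
        far = np.nonzero(dist > 0.05)[0]
        assert far.size, "order parameters never leave the initial point"
        returns = np.nonzero(dist[far[0]:] < 1e-3)[0]
        assert returns.size, "no recurrence: not a limit cycle"
        assert np.ptp(wb[half:]) > 0.05  # genuinely oscillating
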