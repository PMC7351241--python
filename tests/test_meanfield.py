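import math

import numpy as np
import pytest
from scipy.integrate import quad

from stdpmux.stdp_rules import STDPRule, eval_weight_dependence
from stdpmux.synthetic_inputs import PopulationSpec
from stdpmux.stability import eigenvalues, homogeneous_fixed_point
from stdpmux import meanfield as mf

D, DELAY = 10.0, 0.010


def make_specs(n=24, sigma=0.6, gamma=1.0, freqs=(5.0, 9.0)):
    return [PopulationSpec(n, f, gamma=gamma, intensity_mean=D, sigma=sigma) for f in freqs]


class TestOrderParameters:
    def test_uniform_profile(self):
        state = mf.MeanFieldState([np.full(16, 0.3)])
        op = mf.order_parameters(state)
        assert op.w_bar[0] == pytest.approx(0.3)
        assert op.w_tilde[0] == pytest.approx(0.0, abs=1e-15)
        assert op.psi[0] == 0.0

    def test_cosine_profile_half_amplitude(self):
        phis = 2 * math.pi * np.arange(64) / 64
        state = mf.MeanFieldState([0.5 + 0.1 * np.cos(phis - 1.0)])
        op = mf.order_parameters(state)
        assert op.w_bar[0] == pytest.approx(0.5)
        assert op.w_tilde[0] == pytest.approx(0.05)
        assert op.psi[0] == pytest.approx(1.0)

    def test_rotation_shifts_phase_only(self, rng):
        n = 60
        w = rng.uniform(0, 1, n)
        shift = 7  # grid rotation by 2*pi*7/60
        op0 = mf.order_parameters(mf.MeanFieldState([w]))
        op1 = mf.order_parameters(mf.MeanFieldState([np.roll(w, shift)]))
        assert op1.w_bar[0] == pytest.approx(op0.w_bar[0])
        assert op1.w_tilde[0] == pytest.approx(op0.w_tilde[0])
        dpsi = (op1.psi[0] - op0.psi[0]) % (2 * math.pi)
        assert dpsi == pytest.approx(2 * math.pi * shift / n, abs=1e-10)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            mf.order_parameters(mf.MeanFieldState([np.array([])]))


class TestDriftField:
    def test_zero_at_homogeneous_fixed_point(self, asym_rule):
        specs = make_specs()
        fp = homogeneous_fixed_point(asym_rule, DELAY, 0.6, 24, D)
        state = mf.MeanFieldState([np.full(24, fp.w_star) for _ in specs])
        drifts = mf.drift_field(state, asym_rule, specs, DELAY)
        scale = D * D  # typical drift-component magnitude
        for dr in drifts:
            assert np.max(np.abs(dr)) < 1e-10 * scale

    def test_quadrature_oracle(self, asym_rule, rng):
        """Drift equals brute-force quadrature of the correlation-vs-kernel
        integral for every neuron (independent oracle for the closed form)."""
        specs = make_specs(n=12)
        state = mf.MeanFieldState([rng.uniform(0.1, 0.9, 12) for _ in specs])
        drifts = mf.drift_field(state, asym_rule, specs, DELAY)
        ops = mf.order_parameters(state)
        sigma = 0.6
        tp, tm = asym_rule.tau_plus, asym_rule.tau_minus

        def kernel(x, tau, sign):
            if sign * x <= 0:
                return 0.0
            return math.exp(-abs(x) / tau) / tau

        for eta, spec in enumerate(specs):
            other = 1 - eta
            for j in range(spec.size):
                w_j = state.weights[eta][j]
                f_p, f_m = eval_weight_dependence(asym_rule, w_j)

                def gamma_post(lag):
                    # pre-post correlation minus the self-spike delta (handled
                    # analytically below)
                    cos_part = (
                        D * D * (1 + sigma**2)
                        * (ops.w_bar[eta]
                           + 0.5 * spec.gamma**2 * ops.w_tilde[eta]
                           * math.cos(spec.nu * (lag - DELAY) + spec.phases[j] - ops.psi[eta]))
                    )
                    return cos_part + D * D * ops.w_bar[other]

                total = 0.0
                for tau, sign, f in ((tp, +1, f_p), (tm, -1, f_m)):
                    integral = quad(
                        lambda x: gamma_post(x) * kernel(x, tau, sign),
                        -30 * tau if sign < 0 else 0.0,
                        0.0 if sign < 0 else 30 * tau,
                        limit=800,
                    )[0]
                    integral += (D / spec.size) * w_j * kernel(DELAY, tau, sign)
                    total += f * integral if sign > 0 else -f * integral
                assert drifts[eta][j] == pytest.approx(total, rel=1e-6)

    def test_gamma_zero_kills_rhythmic_component(self, asym_rule, rng):
        specs = make_specs(gamma=0.0)
        state = mf.MeanFieldState([rng.uniform(0.2, 0.8, 24) for _ in specs])
        dec = mf.drift_decomposition(state, asym_rule, specs, DELAY)
        for f1 in dec.f_1:
            assert np.all(f1 == 0.0)

    def test_cross_population_coupling_only_via_mean(self, asym_rule, rng):
        """Reshaping population 2 at fixed mean leaves population 1's drift
        unchanged (rhythmic components never interact directly)."""
        specs = make_specs()
        w1 = rng.uniform(0.2, 0.8, 24)
        w2a = rng.uniform(0.2, 0.8, 24)
        w2b = np.roll(w2a, 5)  # same mean, different w_tilde phase
        phis = 2 * math.pi * np.arange(24) / 24
        w2c = np.clip(np.mean(w2a) + 0.2 * np.cos(phis), 0, 1)  # different w_tilde
        w2c += np.mean(w2a) - np.mean(w2c)
        d_a = mf.drift_field(mf.MeanFieldState([w1, w2a]), asym_rule, specs, DELAY)[0]
        d_b = mf.drift_field(mf.MeanFieldState([w1, w2b]), asym_rule, specs, DELAY)[0]
        d_c = mf.drift_field(mf.MeanFieldState([w1, w2c]), asym_rule, specs, DELAY)[0]
        assert np.allclose(d_a, d_b, atol=1e-12)
        assert np.allclose(d_a, d_c, atol=1e-9)

    def test_population_mismatch_rejected(self, asym_rule):
        state = mf.MeanFieldState([np.full(24, 0.5)])
        with pytest.raises(ValueError):
            mf.drift_field(state, asym_rule, make_specs(), DELAY)


class TestIntegration:
    def test_rotational_equivariance(self, asym_rule, rng):
        specs = make_specs(n=30)
        w0 = [rng.uniform(0.3, 0.7, 30) for _ in specs]
        shift = 6
        t1 = mf.integrate_meanfield(
            mf.MeanFieldState([w.copy() for w in w0]), asym_rule, specs, DELAY,
            horizon=50, step=0.5,
        )
        t2 = mf.integrate_meanfield(
            mf.MeanFieldState([np.roll(w, shift) for w in w0]), asym_rule, specs, DELAY,
            horizon=50, step=0.5,
        )
        for a, b in zip(t1.final_state.weights, t2.final_state.weights):
            assert np.allclose(np.roll(a, shift), b, atol=1e-9)

    def test_step_too_large_raises(self, asym_rule):
        specs = make_specs()
        state = mf.initial_state(specs, "random", 0.0, 1.0, rng=0)
        with pytest.raises(mf.IntegrationError):
            mf.integrate_meanfield(state, asym_rule, specs, DELAY, horizon=10, step=5.0)

    def test_weights_stay_bounded(self, asym_rule, rng):
        specs = make_specs(n=20)
        state = mf.initial_state(specs, "random", 0.0, 1.0, rng=1)
        traj = mf.integrate_meanfield(state, asym_rule, specs, DELAY, horizon=200, step=0.5)
        for w in traj.final_state.weights:
            assert np.all((w >= 0) & (w <= 1))
        assert np.all(traj.w_tilde <= traj.w_bar + 1e-12)

    def test_eigenvalue_growth_oracle(self, asym_rule):
        """Linear growth/decay of eigen-perturbations matches the analytic
        rates (lambda*D^2 scaling) — the central cross-module oracle."""
        n = 120
        specs = make_specs(n=n)
        es = eigenvalues(asym_rule, specs, DELAY)
        fp = es.fixed_point
        lam_d2 = asym_rule.learning_rate * D * D
        eps = 1e-4
        phis = 2 * math.pi * np.arange(n) / n

        def measure(w1, w2, observable):
            state = mf.MeanFieldState([w1, w2])
            x0 = observable(state)
            traj = mf.integrate_meanfield(state, asym_rule, specs, DELAY,
                                          horizon=2.0, step=0.05, output_stride=2.0)
            x1 = observable(traj.final_state)
            return math.log(abs(x1 / x0)) / 2.0

        base = np.full(n, fp.w_star)
        # uniform mode (1, 1)
        rate = measure(base + eps, base + eps,
                       lambda s: np.mean(s.weights[0]) + np.mean(s.weights[1]) - 2 * fp.w_star)
        assert rate == pytest.approx(es.lambda_u * lam_d2, rel=0.05)
        # WTA mode (1, -1)
        rate = measure(base + eps, base - eps,
                       lambda s: np.mean(s.weights[0]) - np.mean(s.weights[1]))
        assert rate == pytest.approx(es.lambda_wta * lam_d2, rel=0.05)
        # rhythmic modes: growth rate of w_tilde matches the dynamics-consistent
        # eigenvalue (the closed form with the gamma^2/4 coefficient)
        for eta, f in enumerate((5.0, 9.0)):
            w = [base.copy(), base.copy()]
            w[eta] = base + eps * np.cos(phis)
            rate = measure(w[0], w[1],
                           lambda s, e=eta: mf.order_parameters(s).w_tilde[e])
            assert rate == pytest.approx(es.lambda_rhythmic_dyn[f] * lam_d2, rel=0.05)


class TestPhaseVelocity:
    def _traj(self, times, w_tilde, psi):
        n = len(times)
        return mf.MeanFieldTrajectory(
            times=np.asarray(times, dtype=float),
            w_bar=np.full((n, 1), 0.5),
            w_tilde=np.asarray(w_tilde).reshape(n, 1),
            psi=np.asarray(psi).reshape(n, 1),
            final_state=mf.MeanFieldState([np.full(8, 0.5)]),
        )

    def test_synthetic_linear_drift(self):
        t = np.arange(0, 100.0)
        traj = self._traj(t, np.full_like(t, 0.2), (0.3 * t) % (2 * math.pi))
        out = mf.phase_velocity(traj, window=80.0)
        assert out[0]["defined"]
        assert out[0]["velocity"] == pytest.approx(0.3, abs=1e-9)
        assert out[0]["residual_rms"] == pytest.approx(0.0, abs=1e-9)

    def test_undefined_below_floor(self):
        t = np.arange(0, 50.0)
        traj = self._traj(t, np.full_like(t, 1e-4), np.zeros_like(t))
        out = mf.phase_velocity(traj, window=40.0)
        assert not out[0]["defined"]

    def test_window_too_short(self):
        t = np.arange(0, 50.0)
        traj = self._traj(t, np.full_like(t, 0.2), np.zeros_like(t))
        with pytest.raises(ValueError):
            mf.phase_velocity(traj, window=1.0)


def test_frozen_profile_downstream_rate(asym_rule):
    """A frozen cosine profile must feed the linear neuron the closed-form
    rate D*w_bar + D*gamma*w_tilde*cos(nu (t-d) - psi) per population."""
    n = 48
    specs = make_specs(n=n, freqs=(5.0,))
    phis = 2 * math.pi * np.arange(n) / n
    w = 0.4 + 0.2 * np.cos(phis - 0.7)  # w_tilde = 0.1, psi = 0.7
    op = mf.order_parameters(mf.MeanFieldState([w]))
    spec = specs[0]
    for t in np.linspace(0, 0.4, 13):
        direct = np.mean(w * D * (1 + spec.gamma * np.cos(spec.nu * (t - DELAY) - phis)))
        formula = D * op.w_bar[0] + D * spec.gamma * op.w_tilde[0] * math.cos(
            spec.nu * (t - DELAY) - op.psi[0]
        )
        assert direct == pytest.approx(formula, abs=1e-6)
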