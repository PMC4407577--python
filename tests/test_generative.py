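"""Forward model: neural dynamics, hemodynamics, BOLD observation and
their RK4 integration."""

import numpy as np
import pytest

import emodcm as e
from emodcm.generative import (DCMParameters, bold_observe,
                               hemodynamic_derivative, neural_derivative)
from emodcm.model_space import INPUT_INDEX, REGION_INDEX


def one_region_params(a=-0.5, b_neg=0.0, c=0.0):
    """Scalar reduction of the network for hand-checkable derivatives."""
    p = DCMParameters(A=np.array([[a]]),
                      B=np.array([[[b_neg]]]),
                      C=np.array([[c]]),
                      D=np.zeros((1, 1, 1)),
                      kappa=np.array([0.64]), tau=np.array([2.0]))
    return p


class TestNeuralDerivative:
    def test_rest_is_fixed_point(self, group_params):
        dz = neural_derivative(np.zeros(6), np.zeros(3), group_params)
        assert np.allclose(dz, 0)

    def test_single_region_decay(self):
        p = one_region_params(a=-0.5)
        assert neural_derivative([1.0], [0.0], p) == pytest.approx(-0.5)

    def test_bilinear_modulation(self):
        # (A + u B) z = (-0.5 + 1*0.2) * 1 = -0.3
        p = one_region_params(a=-0.5, b_neg=0.2)
        assert neural_derivative([1.0], [1.0], p) == pytest.approx(-0.3)

    def test_linear_in_state_without_gating(self, group_params):
        rng = np.random.default_rng(0)
        z = rng.normal(size=6)
        u = np.array([1.0, 0.0, 1.0])
        d1 = neural_derivative(z, u, group_params)
        d2 = neural_derivative(2 * z, u, group_params)
        drive = group_params.C @ u
        assert np.allclose(d2 - drive, 2 * (d1 - drive))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            neural_derivative([np.nan], [0.0], one_region_params())


class TestHemodynamicDerivative:
    def test_baseline_fixed_point(self):
        p = one_region_params()
        d = hemodynamic_derivative(np.array([0.0, 1.0, 1.0, 1.0]), 0.0, p)
        assert np.allclose(d, 0)

    def test_signal_decay(self):
        p = one_region_params()
        d = hemodynamic_derivative(np.array([0.1, 1.0, 1.0, 1.0]), 0.0, p)
        assert d[0] == pytest.approx(-0.064)  # -kappa * s

    def test_inflow_follows_signal(self):
        p = one_region_params()
        rng = np.random.default_rng(1)
        for _ in range(20):
            s = rng.normal()
            state = np.array([s, *np.exp(rng.normal(0, 0.1, 3))])
            d = hemodynamic_derivative(state, rng.normal(), p)
            assert d[1] == s

    def test_domain_guard(self):
        with pytest.raises(ValueError, match="admissible"):
            hemodynamic_derivative(np.array([0.0, -1.0, 1.0, 1.0]), 0.0,
                                   one_region_params())


class TestBoldObserve:
    def test_baseline_zero(self, group_params):
        assert bold_observe(1.0, 1.0, group_params) == 0.0

    def test_hand_value(self, group_params):
        # V0 (k1 (1-q) + k2 (1-q/v)) = 0.02 (2.38*0.1 + 2*0.1)
        y = bold_observe(1.0, 0.9, group_params)
        assert y == pytest.approx(0.00876)

    def test_decreasing_in_deoxyhemoglobin(self, group_params):
        qs = np.linspace(0.5, 1.5, 30)
        for v in (0.8, 1.0, 1.3):
            ys = bold_observe(v, qs, group_params)
            assert np.all(np.diff(ys) < 0)


class TestSimulateBold:
    def test_rest_invariance(self, bu_singleton, small_inputs):
        p = e.default_group_parameters(bu_singleton)
        p.C[:] = 0.0
        ts = e.simulate_bold(p, small_inputs)
        assert np.allclose(ts.data, 0.0, atol=1e-12)

    def test_observation_scale_linear_in_v0(self, bu_singleton, small_inputs,
                                            group_params):
        ts1 = e.simulate_bold(group_params, small_inputs, bu_singleton)
        p2 = group_params.copy()
        p2.v0 *= 2
        ts2 = e.simulate_bold(p2, small_inputs, bu_singleton)
        assert np.allclose(ts2.data, 2 * ts1.data, rtol=1e-9, atol=1e-14)

    def test_single_event_peak_latency(self, bu_singleton):
        """An isolated 3.5 s face evokes an IOG response peaking with the
        canonical hemodynamic lag: about 2 s of sustained-stimulus shift
        on top of the 4-6 s impulse peak (simulation places it at 7.8 s
        post-onset with the default constants)."""
        import pandas as pd
        ev = pd.DataFrame([(12.0, 3.5, "neutral", 0, 0)],
                          columns=["onset", "duration", "trial_type", "run",
                                   "face_id"])
        inputs = e.events_to_inputs(ev, dt=0.15, n_runs=1,
                                    scans_per_run=120, tr=0.6)
        p = e.default_group_parameters(bu_singleton)
        ts = e.simulate_bold(p, inputs, bu_singleton)
        iog = ts.data[:, REGION_INDEX["IOG"]]
        t_peak = np.argmax(iog) * 0.6 - 12.0
        assert 4.0 <= t_peak <= 8.0

    def test_neural_linearity_small_drive(self, bu_singleton, small_inputs):
        """With B = D = 0 the neural stage is linear; the observation
        nonlinearity vanishes proportionally with drive amplitude
        (measured deviations ~ 1.04 * C for this design)."""
        def halving_deviation(c):
            p = e.default_group_parameters(bu_singleton)
            p.B[:] = 0.0
            p.C[:] = 0.0
            p.C[REGION_INDEX["IOG"], INPUT_INDEX["all_faces"]] = c
            y_full = e.simulate_bold(p, small_inputs).data
            p.C[REGION_INDEX["IOG"], INPUT_INDEX["all_faces"]] = c / 2
            y_half = e.simulate_bold(p, small_inputs).data
            return (np.linalg.norm(y_full / 2 - y_half)
                    / np.linalg.norm(y_full / 2))

        d1 = halving_deviation(0.1)
        d2 = halving_deviation(0.025)
        assert d1 < 0.12
        assert d2 < 0.036
        assert d2 < d1 / 2  # deviation shrinks at least linearly

    def test_integrator_convergence(self, bu_singleton, small_design,
                                    group_params):
        fine = e.events_to_inputs(small_design, dt=2.4 / 16, n_runs=1,
                                  scans_per_run=60)
        finer = e.events_to_inputs(small_design, dt=2.4 / 32, n_runs=1,
                                   scans_per_run=60)
        y1 = e.simulate_bold(group_params, fine).data
        y2 = e.simulate_bold(group_params, finer).data
        assert np.abs(y1 - y2).max() < 1e-3

    def test_td_gating_zero_reduces_to_bilinear(self, small_inputs):
        td = e.enumerate_top_down()[0]
        p = e.default_group_parameters(td)
        p.D[:] = 0.0
        y_td = e.simulate_bold(p, small_inputs).data
        p2 = p.copy()
        y_ref = e.simulate_bold(p2, small_inputs).data
        assert np.array_equal(y_td, y_ref)
        # and gating genuinely changes the output when switched on
        p3 = e.default_group_parameters(td)
        y_gated = e.simulate_bold(p3, small_inputs, td).data
        assert np.abs(y_gated - y_td).max() > 0

    def test_blowup_reported_with_time(self, bu_singleton, small_inputs):
        p = e.default_group_parameters(bu_singleton)
        p.A += 2.0 * (~np.eye(6, dtype=bool))  # wildly unstable coupling
        with pytest.raises(RuntimeError, match="t = "):
            e.simulate_bold(p, small_inputs)

    def test_kernel_matches_reference_rk4(self, bu_singleton, group_params):
        """The JIT kernel reproduces a transparent pure-python RK4 of the
        same log-state equations."""
        import pandas as pd
        ev = pd.DataFrame([(5.0, 3.5, "negative", 0, 0),
                           (15.0, 3.5, "neutral", 0, 1)],
                          columns=["onset", "duration", "trial_type", "run",
                                   "face_id"])
        inputs = e.events_to_inputs(ev, dt=0.3, n_runs=1, scans_per_run=15)
        y_kernel = e.simulate_bold(group_params, inputs).data

        p = group_params

        def deriv(x, u):
            z, s = x[:6], x[6:12]
            f, v, q = np.exp(x[12:18]), np.exp(x[18:24]), np.exp(x[24:30])
            dz = neural_derivative(z, u, p)
            ds = z - p.kappa * s - p.gamma * (f - 1)
            dlf = s / f
            ia = 1 / p.alpha
            dlv = (f - v ** ia) / (p.tau * v)
            eef = 1 - (1 - p.rho) ** (1 / f)
            dlq = (f * eef / (p.rho * q) - v ** (ia - 1)) / p.tau
            return np.concatenate([dz, ds, dlf, dlv, dlq])

        x = np.zeros(30)
        dt = 0.3
        y_ref = np.zeros((15, 6))
        for scan in range(1, 15):
            for sub in range(8):
                u = inputs.u[(scan - 1) * 8 + sub]
                k1 = deriv(x, u)
                k2 = deriv(x + dt / 2 * k1, u)
                k3 = deriv(x + dt / 2 * k2, u)
                k4 = deriv(x + dt * k3, u)
                x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            v, q = np.exp(x[18:24]), np.exp(x[24:30])
            k1c, k2c, k3c = 7 * p.rho, 2.0, 2 * p.rho - 0.2
            y_ref[scan] = p.v0 * (k1c * (1 - q) + k2c * (1 - q / v)
                                  + k3c * (1 - v))
        assert np.allclose(y_kernel, y_ref, atol=1e-12)


class TestParameterValidation:
    def test_mask_violation_rejected(self, bu_singleton):
        p = e.default_group_parameters(bu_singleton)
        p.D[0, 1, 2] = 0.3
        with pytest.raises(ValueError, match="D nonzero"):
            p.validate(bu_singleton)

    def test_physiological_ranges(self, group_params):
        p = group_params.copy()
        p.rho = 1.5
        with pytest.raises(ValueError):
            p.validate()
        p = group_params.copy()
        p.A[0, 0] = 0.1
        with pytest.raises(ValueError):
            p.validate()
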