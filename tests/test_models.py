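"""Cell-model contract tests: reference equivalence, resting stability,
Euler convergence, conductance linearity and clamped/free consistency."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ctclab.exceptions import BoundsError, SimulationBlowupError
from ctclab.metrics import apd_amplitude, apd_mouse80
from ctclab.models import SimSettings, StimulusProtocol
from ctclab.models.human import STATE_NAMES as H_STATES, make_human_recipient_model
from ctclab.models.human import PARAM_NAMES as H_PARAMS
from ctclab.models.mouse import (PARAM_NAMES as M_PARAMS,
                                 STATE_NAMES as M_STATES,
                                 make_neonatal_mouse_model, stimulus_amplitude)

from reference_models import (human_reference_current, human_reference_run,
                              mouse_reference_current, mouse_reference_run)


def _mouse_dicts(params, state):
    p = {n: params[n] for n in M_PARAMS}
    s = {n: float(v) for n, v in zip(M_STATES, state)}
    return p, s


def _human_dicts(params, state):
    p = {n: params[n] for n in H_PARAMS}
    s = {n: float(v) for n, v in zip(H_STATES, state)}
    return p, s


class TestMouseModel:
    def test_baseline_has_stated_sodium_conductance_and_concentrations(self, mouse_model):
        _, params = mouse_model
        assert params["g_Na"] == pytest.approx(0.8)
        assert params["K_o"] == 5.4 and params["Na_o"] == 140.0
        assert params["Ca_o"] == 1.2 and params["Na_i"] == 8.6
        assert params["K_i"] == 142.0 and params["Ca_i"] == pytest.approx(7.9e-5)

    def test_zero_genotype_is_identity(self, mouse_model):
        from ctclab.ga import Genotype

        _, base = mouse_model
        _, scaled = make_neonatal_mouse_model(Genotype.zeros())
        np.testing.assert_array_equal(base.values, scaled.values)

    def test_out_of_bounds_genotype_rejected(self):
        from ctclab.ga import Genotype

        with pytest.raises(BoundsError):
            make_neonatal_mouse_model(Genotype(np.array([0.95, 0, 0, 0, 0, 0])))

    def test_resting_state_is_quiescent(self, mouse_model):
        model, _ = mouse_model
        trace = model.simulate_paced(
            protocol=StimulusProtocol(amplitude=0.0, onset=50.0),
            settings=SimSettings(dt=0.1, beats=1))
        assert np.max(np.abs(trace.v - trace.v[0])) < 1.0

    def test_free_step_is_fixed_point_at_rest(self, mouse_model):
        model, _ = mouse_model
        y0 = model.initial_state.copy()
        y1 = model.step_free(y0, 0.0, 0.1)
        assert abs(y1[0] - y0[0]) < 1e-6

    def test_clamped_step_fixed_point_at_rest(self, mouse_model):
        model, _ = mouse_model
        y0 = model.initial_state.copy()
        y1 = model.step_clamped(y0, float(y0[0]), 0.1)
        np.testing.assert_allclose(y1, y0, atol=1e-9)

    def test_suprathreshold_pulse_fires_with_overshoot(self, mouse_baseline_trace):
        from ctclab.metrics import apd_report

        rep = apd_report(mouse_baseline_trace)
        assert rep.peak > 0.0

    def test_subthreshold_pulse_does_not_fire(self, mouse_model):
        model, _ = mouse_model
        weak = StimulusProtocol(amplitude=stimulus_amplitude() / 3.0, onset=50.0)
        trace = model.simulate_paced(weak, SimSettings(dt=0.1, beats=1))
        assert trace.v.max() < -20.0

    def test_consecutive_beats_are_quasi_stationary(self, mouse_baseline_trace):
        # after a couple of adaptation beats (the slowly inactivating K+
        # gate, tau ~ 2.1 s, settles toward its paced state)
        a2 = apd_mouse80(mouse_baseline_trace, beat=2)
        a3 = apd_mouse80(mouse_baseline_trace, beat=3)
        assert abs(a3 - a2) < 2.0

    def test_reference_equivalence_current_and_trajectory(self, mouse_model):
        model, params = mouse_model
        proto = model.default_protocol()
        n = int(round(1000.0 / 0.1))
        p, s0 = _mouse_dicts(params, model.initial_state)
        ref_v, _ = mouse_reference_run(p, s0, model.initial_state[0], 0.1, n,
                                       proto.onset, proto.duration,
                                       proto.amplitude)
        trace = model.simulate_paced(proto, SimSettings(dt=0.1, beats=1))
        scale = np.max(np.abs(ref_v))
        np.testing.assert_allclose(trace.v[:n + 1], ref_v, rtol=0,
                                   atol=1e-6 * scale)

    def test_reference_equivalence_pointwise_current(self, mouse_model, rng):
        model, params = mouse_model
        for _ in range(50):
            y = model.initial_state.copy()
            y[1:] = rng.uniform(0.02, 0.98, size=y.size - 1)
            v = rng.uniform(-120.0, 60.0)
            p, s = _mouse_dicts(params, y)
            ref = mouse_reference_current(p, s, v)
            assert model.ionic_current(y, v) == pytest.approx(ref, rel=1e-12)

    def test_euler_convergence_of_apd(self, mouse_model):
        model, _ = mouse_model
        apds = {}
        for dt in (0.1, 0.05):
            tr = model.simulate_paced(settings=SimSettings(dt=dt, beats=1))
            apds[dt] = apd_mouse80(tr)
        assert abs(apds[0.1] - apds[0.05]) < 0.5

    def test_conductance_linearity(self, mouse_model, rng):
        model, params = mouse_model
        y = model.initial_state.copy()
        y[1:] = rng.uniform(0.05, 0.95, size=y.size - 1)
        v = -20.0
        doubled = params.copy()
        doubled["g_ss"] = 2.0 * params["g_ss"]
        m2, _ = make_neonatal_mouse_model(base_params=doubled)
        base_i = model.ionic_current(y, v)
        # the g_ss component is the difference; doubling again must double it
        comp = m2.ionic_current(y, v) - base_i
        tripled = params.copy()
        tripled["g_ss"] = 3.0 * params["g_ss"]
        m3, _ = make_neonatal_mouse_model(base_params=tripled)
        assert m3.ionic_current(y, v) - base_i == pytest.approx(2.0 * comp, rel=1e-12)

    def test_nernst_reversal_of_pure_potassium_currents(self, mouse_model):
        """I_ss and I_t vanish exactly at the K+ Nernst potential."""
        model, params = mouse_model
        e_k = 8314.5 * params["T"] / 96487.0 * np.log(params["K_o"] / params["K_i"])
        only = params.copy()
        for name in ("g_Na", "g_CaL", "g_t", "g_Kslow", "g_K1", "g_f", "g_B_Na",
                     "g_B_Ca", "g_B_K"):
            only[name] = 0.0
        only["i_NaK_max"] = 0.0
        only["k_NaCa"] = 0.0
        only["i_CaP_max"] = 0.0
        m_ss, _ = make_neonatal_mouse_model(base_params=only)
        y = model.initial_state.copy()
        y[11] = y[12] = 0.5
        # the residual is the small K+ background term of the IK1 formula,
        # not carried by any conductance parameter
        assert m_ss.ionic_current(y, e_k) == pytest.approx(0.0, abs=1e-4)
        # the g_ss-carried component itself is exactly zero at E_K
        more = only.copy()
        more["g_ss"] = 2.0 * only["g_ss"]
        m2, _ = make_neonatal_mouse_model(base_params=more)
        assert m2.ionic_current(y, e_k) == m_ss.ionic_current(y, e_k)

    def test_inward_rectifier_reverses_near_nernst(self, mouse_model):
        model, params = mouse_model
        e_k = 8314.5 * params["T"] / 96487.0 * np.log(params["K_o"] / params["K_i"])
        only = params.copy()
        for name in ("g_Na", "g_CaL", "g_t", "g_Kslow", "g_ss", "g_f", "g_B_Na",
                     "g_B_Ca", "g_B_K"):
            only[name] = 0.0
        only["i_NaK_max"] = only["k_NaCa"] = only["i_CaP_max"] = 0.0
        mk1, _ = make_neonatal_mouse_model(base_params=only)
        y = model.initial_state.copy()
        below = mk1.ionic_current(y, e_k - 3.0)
        above = mk1.ionic_current(y, e_k + 3.0)
        assert below < 0.0 < above

    @given(v=st.floats(min_value=-150.0, max_value=80.0))
    def test_gates_stay_in_unit_interval_under_clamp(self, mouse_model, v):
        model, _ = mouse_model
        y = model.initial_state.copy()
        for _ in range(50):
            y = model.step_clamped(y, v, 0.1)
        assert np.all(y[1:] >= 0.0) and np.all(y[1:] <= 1.0)

    def test_clamped_replay_reproduces_free_running_gates(self, mouse_model):
        model, _ = mouse_model
        proto = model.default_protocol()
        y_free = model.initial_state.copy()
        y_clamp = model.initial_state.copy()
        dt = 0.1
        for k in range(3000):
            t = k * dt
            v_pre = float(y_free[0])
            amp = proto.amplitude if proto.onset <= t < proto.onset + proto.duration else 0.0
            y_free = model.step_free(y_free, -amp, dt)
            y_clamp = model.step_clamped(y_clamp, v_pre, dt)
            np.testing.assert_allclose(y_clamp[1:], y_free[1:], rtol=0, atol=1e-12)

    def test_nonfinite_state_raises_with_dump(self, mouse_model):
        model, _ = mouse_model
        y = model.initial_state.copy()
        y[3] = np.nan
        with pytest.raises(SimulationBlowupError):
            model.ionic_current(y, -80.0)

    def test_fast_exp_variant_is_close_to_exact(self, mouse_model):
        model, _ = mouse_model
        fast = model.with_settings(use_fast_exp=True)
        tr_exact = model.simulate_paced(settings=SimSettings(dt=0.1, beats=1))
        tr_fast = fast.simulate_paced(settings=SimSettings(dt=0.1, beats=1,
                                                           use_fast_exp=True))
        assert abs(apd_mouse80(tr_fast) - apd_mouse80(tr_exact)) < 0.5


class TestHumanModel:
    def test_resting_state_is_quiescent(self, human_model):
        model, _ = human_model
        trace = model.simulate_paced(
            protocol=StimulusProtocol(amplitude=0.0, onset=50.0),
            settings=SimSettings(dt=0.01, beats=1))
        assert np.max(np.abs(trace.v - trace.v[0])) < 1.0

    def test_paced_ap_has_human_plateau_morphology(self, human_trace):
        apd90 = apd_amplitude(human_trace, 90)
        assert 200.0 < apd90 < 500.0
        assert human_trace.v.max() > 20.0

    def test_reference_equivalence_apd90_and_trajectory(self, human_model):
        model, params = human_model
        proto = model.default_protocol()
        dt = 0.01
        n = int(round(600.0 / dt))
        p, s0 = _human_dicts(params, model.initial_state)
        ref_v, _ = human_reference_run(p, s0, model.initial_state[0], dt, n,
                                       proto.onset, proto.duration,
                                       proto.amplitude)
        trace = model.simulate_paced(proto, SimSettings(dt=dt, beats=1))
        scale = np.max(np.abs(ref_v))
        np.testing.assert_allclose(trace.v[:n + 1], ref_v, rtol=0,
                                   atol=1e-6 * scale)
        from ctclab.trace import VoltageTrace

        ref_trace = VoltageTrace(0.0, dt, np.asarray(ref_v),
                                 np.array([proto.onset]))
        assert apd_amplitude(trace, 90) == pytest.approx(
            apd_amplitude(ref_trace, 90), abs=1.0)

    def test_reference_equivalence_pointwise_current(self, human_model, rng):
        model, params = human_model
        for _ in range(50):
            y = model.initial_state.copy()
            y[1:13] = rng.uniform(0.02, 0.98, size=12)
            y[13] = rng.uniform(5e-5, 5e-4)
            y[14] = rng.uniform(0.2, 2.0)
            v = rng.uniform(-120.0, 60.0)
            p, s = _human_dicts(params, y)
            ref = human_reference_current(p, s, v)
            assert model.ionic_current(y, v) == pytest.approx(ref, rel=1e-12)

    def test_euler_convergence_of_apd90(self, human_model):
        model, _ = human_model
        apds = {}
        for dt in (0.01, 0.005):
            tr = model.simulate_paced(settings=SimSettings(dt=dt, beats=1))
            apds[dt] = apd_amplitude(tr, 90)
        assert abs(apds[0.01] - apds[0.005]) < 0.5

    def test_blowup_reports_failing_time(self, human_model):
        model, _ = human_model
        huge = StimulusProtocol(period=1000.0, duration=500.0, amplitude=5000.0,
                                onset=10.0)
        with pytest.raises(SimulationBlowupError) as err:
            model.simulate_paced(huge, SimSettings(dt=0.01, beats=1))
        assert np.isfinite(err.value.time_ms)


class TestParameterSet:
    def test_json_round_trip_preserves_values_and_units(self, mouse_model):
        from ctclab.models import ParameterSet

        _, params = mouse_model
        clone = ParameterSet.from_json(params.to_json())
        np.testing.assert_array_equal(clone.values, params.values)
        assert clone.unit_of("g_Na") == "uS"
        assert clone.unit_of("Na_o") == "mM"

    def test_validation_rejects_negative_conductance(self, mouse_model):
        _, params = mouse_model
        bad = params.copy()
        bad["g_t"] = -0.01
        with pytest.raises(BoundsError):
            bad.validate()
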