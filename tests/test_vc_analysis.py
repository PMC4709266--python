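"""Voltage-clamp analysis: I-V extraction, slope conductance, tail-current
activation curves, Boltzmann fits, subtraction, and recording corrections."""

import numpy as np
import pytest

from ihc_encode.model import SweepSet, make_condition, simulate
from ihc_encode.protocols import StepProtocol, make_vc_steps, render
from ihc_encode.trace import Trace
from ihc_encode.vc_analysis import (
    ActivationCurve,
    IVCurve,
    RecordingParams,
    fit_boltzmann,
    holding_current_shift,
    junction_correct,
    measure_iv,
    slope_conductance,
    subtract_conditions,
    tail_activation,
    vc_time_constant,
)

from conftest import make_toy_preset, single_channel_preset

CA13 = make_condition("Ca1.3")
LOW = make_condition("lowCa40")


def _synthetic_sweepset(responses_fn, protocol=None):
    """SweepSet whose response samples come from responses_fn(level, t_s)."""
    p = protocol or make_vc_steps(-104, -24, 20, pre_duration=20,
                                  step_duration=170, tail_duration=50)
    stimuli, responses = [], []
    for i, level in enumerate(p.step_levels):
        stim = render(p, i)
        t = stim.times()
        responses.append(Trace(0.0, stim.dt, responses_fn(level, t), unit="pA"))
        stimuli.append(stim)
    return SweepSet(protocol=p, stimuli=stimuli, responses=responses)


class TestMeasureIV:
    def test_constant_response_gives_flat_curves(self):
        sweeps = _synthetic_sweepset(lambda lv, t: np.full(t.size, 200.0))
        for measure in ("peak_2ms", "ss_160ms"):
            iv = measure_iv(sweeps, measure)
            assert np.allclose(iv.I, 200.0)
            assert np.all(np.diff(iv.V) > 0)

    def test_slow_exponential_rise_orders_peak_below_steady_state(self):
        tau = 0.050  # s

        def rise(level, t):
            on = 0.020
            y = np.zeros(t.size)
            m = t >= on
            y[m] = level * (1 - np.exp(-(t[m] - on) / tau))
            return y

        sweeps = _synthetic_sweepset(rise)
        peak = measure_iv(sweeps, "peak_2ms")
        ss = measure_iv(sweeps, "ss_160ms")
        # oracle: the generating exponential evaluated at both times
        for v, ip, iss in zip(peak.V, peak.I, ss.I):
            assert ip == pytest.approx(v * (1 - np.exp(-0.002 / tau)), rel=0.01)
            assert iss == pytest.approx(v * (1 - np.exp(-0.160 / tau)), rel=0.01)
            assert abs(ip) < abs(iss)

    def test_zero_conductance_cell_reads_zero_current(self):
        cell = make_toy_preset(g_leak=0.0)
        sweeps = simulate(cell, LOW, make_vc_steps(), noise=False)
        for measure in ("peak_2ms", "ss_160ms"):
            assert np.all(np.abs(measure_iv(sweeps, measure).I) < 0.1)

    def test_short_step_rejects_steady_state_window(self):
        p = make_vc_steps(step_duration=100.0)
        sweeps = _synthetic_sweepset(lambda lv, t: np.zeros(t.size), protocol=p)
        with pytest.raises(ValueError, match="too short"):
            measure_iv(sweeps, "ss_160ms")


class TestSlopeConductance:
    def test_exact_lines(self):
        v = np.arange(-144.0, 37.0, 10.0)
        assert slope_conductance(IVCurve(v, 10.0 * (v + 64), "ss_160ms"), -64.0) \
            == pytest.approx(10.0)
        assert slope_conductance(IVCurve(v, 56.3 * (v + 54), "ss_160ms"), -54.0) \
            == pytest.approx(56.3)

    def test_invariant_under_current_offset(self):
        v = np.arange(-144.0, 37.0, 10.0)
        i = 7.5 * v + 0.02 * v**2
        g0 = slope_conductance(IVCurve(v, i, "ss_160ms"), -64.0)
        g1 = slope_conductance(IVCurve(v, i + 500.0, "ss_160ms"), -64.0)
        assert g1 == pytest.approx(g0, abs=1e-9)

    def test_symmetric_quadratic_has_zero_slope_at_vertex(self):
        v = np.arange(-144.0, 37.0, 10.0)
        iv = IVCurve(v, 0.3 * (v + 64.0) ** 2, "ss_160ms")
        assert slope_conductance(iv, -64.0) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_points_in_window(self):
        iv = IVCurve(np.array([-144.0, -64.0, 36.0]), np.zeros(3), "ss_160ms")
        with pytest.raises(ValueError, match="2 I-V points"):
            slope_conductance(iv, -104.0)


class TestTailActivation:
    def test_constant_tail_recovers_constant(self):
        sweeps = _synthetic_sweepset(lambda lv, t: np.full(t.size, lv * 2.0))
        act = tail_activation(sweeps)
        assert np.allclose(act.I_tail, act.V_pre * 2.0, rtol=1e-6)
        assert act.tail_V == -124.0

    def test_identical_sweeps_give_flat_curve(self):
        sweeps = _synthetic_sweepset(lambda lv, t: np.full(t.size, -50.0))
        assert np.allclose(tail_activation(sweeps).I_tail, -50.0, rtol=1e-6)

    def test_missing_tail_segment_rejected(self):
        p = StepProtocol(mode="VC", holding_level=-64, pre_duration=20,
                         step_levels=(-64.0,), step_duration=170)
        sweeps = _synthetic_sweepset(lambda lv, t: np.zeros(t.size), protocol=p)
        with pytest.raises(ValueError, match="tail"):
            tail_activation(sweeps)

    @pytest.mark.parametrize("seed", range(5))
    def test_gating_parameter_recovery_from_simulated_tails(self, seed):
        """Round trip: a random single-conductance cell, simulated through
        the standard tail protocol, yields an activation curve whose
        Boltzmann fit recovers the generating V_half within 1 mV and S
        within 5% (noise-free)."""
        rng = np.random.default_rng(1000 + seed)
        preset = single_channel_preset(rng)
        gp = preset.gated[0].gating
        proto = make_vc_steps(-144, 16, 10, sample_rate=20_000.0)
        sweeps = simulate(preset, CA13, proto, noise=False)
        fit = fit_boltzmann(tail_activation(sweeps))
        assert fit.V_half == pytest.approx(gp.V_half, abs=1.0)
        assert fit.S == pytest.approx(gp.S, rel=0.05)


class TestBoltzmannFit:
    @staticmethod
    def _exact_curve():
        v = np.arange(-134.0, -33.0, 10.0)
        i = 500.0 / (1 + np.exp((-85.0 - v) / 9.0))
        return ActivationCurve(v, i, tail_V=-124.0)

    def test_exact_data_recovered_to_machine_precision(self):
        fit = fit_boltzmann(self._exact_curve())
        assert fit.V_half == pytest.approx(-85.0, abs=1e-5)
        assert fit.S == pytest.approx(9.0, rel=1e-6)
        assert fit.I_max == pytest.approx(500.0, rel=1e-6)
        assert fit.rms_residual < 1e-6

    def test_corrupted_point_leaves_parameters_close(self):
        curve = self._exact_curve()
        curve.I_tail[2] = -curve.I_tail[2]
        fit = fit_boltzmann(curve)
        assert fit.rms_residual > 0
        assert fit.V_half == pytest.approx(-85.0, rel=0.05)
        assert fit.S == pytest.approx(9.0, rel=0.05)

    def test_three_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4 points"):
            fit_boltzmann(ActivationCurve(np.array([-100.0, -80.0, -60.0]),
                                          np.array([0.0, 250.0, 500.0]), -124.0))


class TestSubtraction:
    def test_self_subtraction_is_zero(self, basal):
        proto = make_vc_steps(-104, -44, 20)
        sweeps = simulate(basal, CA13, proto, noise=False)
        diff = subtract_conditions(sweeps, sweeps)
        assert all(np.all(r.samples == 0.0) for r in diff.responses)

    def test_isolates_linopirdine_sensitive_current(self, basal):
        """IbTx minus (IbTx + linopirdine) equals the K_n current computed
        directly from the recorded gating states (< 0.5 pA, noise-free)."""
        proto = make_vc_steps(-144, -24, 20)
        kw = dict(seed=None, record_gating=True, response_filter=None, noise=False)
        ibtx = simulate(basal, make_condition("Ca1.3", ibtx=True), proto, **kw)
        both = simulate(basal, make_condition("Ca1.3", ibtx=True,
                                              linopirdine=True), proto, **kw)
        diff = subtract_conditions(ibtx, both)
        for i, stim in enumerate(ibtx.stimuli):
            v = stim.samples
            direct = np.zeros_like(v)
            for name in ("K_n_neg", "K_n_pos"):
                c = basal.conductance(name)
                direct += c.g_max * ibtx.gating[i][name] * (v - c.E_rev)
            assert np.max(np.abs(diff.responses[i].samples - direct)) < 0.5

    def test_mismatched_sweep_counts_rejected(self, basal):
        a = simulate(basal, CA13, make_vc_steps(-104, -44, 20), noise=False)
        b = simulate(basal, CA13, make_vc_steps(-104, -64, 20), noise=False)
        with pytest.raises(ValueError, match="protocol"):
            subtract_conditions(a, b)


class TestHoldingShiftAndCorrections:
    def test_shift_arithmetic(self):
        mk = lambda level: Trace(0.0, 1e-3, np.full(100, level), unit="pA")
        assert holding_current_shift(mk(-50.0), mk(-600.0), (10, 90)) == -550.0
        assert holding_current_shift(mk(-50.0), mk(-50.0), (10, 90)) == 0.0

    def test_unit_mismatch_rejected(self):
        a = Trace(0.0, 1e-3, np.zeros(100), unit="pA")
        b = Trace(0.0, 1e-3, np.zeros(100), unit="mV")
        with pytest.raises(ValueError, match="unit"):
            holding_current_shift(a, b, (10, 90))

    def test_junction_corrections(self):
        assert junction_correct(-60.0, RecordingParams(1.0, 10.0, "KCl")) == -64.0
        assert junction_correct(-60.0, RecordingParams(1.0, 10.0, "K_aspartate")) == -70.0
        override = RecordingParams(1.0, 10.0, "KCl", junction_potential=0.0)
        assert junction_correct(0.0, override) == 0.0
        with pytest.raises(ValueError, match="already"):
            junction_correct(-60.0, RecordingParams(1.0, 10.0), already_corrected=True)

    @pytest.mark.parametrize("rs,cm,expected", [
        (1.0, 10.0, 10.0),
        (1.16, 12.4, 14.384),  # ~ the apical-cell mean clamp time constant
        (1.15, 11.7, 13.455),
    ])
    def test_clamp_time_constant_product(self, rs, cm, expected):
        assert vc_time_constant(RecordingParams(rs, cm)) == pytest.approx(expected)
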