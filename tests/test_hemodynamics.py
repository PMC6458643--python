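"""Central pressure calibration, windkessel compliance and wave intensity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortakit import hemodynamics as hd
from aortakit import synthetic as syn
from aortakit.core import Waveform


def _pressure_wave(alpha=5.0, p_d=70.0, a_d=4.0, hr_bpm=60.0, amp_frac=0.12):
    """Pressure cycle and its exact exponential-model area counterpart."""
    period = 60.0 / hr_bpm
    n = 128
    dt = period / n
    t = np.arange(n) * dt
    u = np.clip(t / (0.55 * period), 0, 1)
    x = amp_frac * np.sin(np.pi * u)          # A/A_d - 1, peak = amp_frac
    p = Waveform(p_d * np.exp(alpha * x), dt, "mmHg")
    a = syn.generate_area_from_pressure(p, alpha, a_d, p_d)
    return p, a


class TestPressureCalibration:
    @pytest.mark.parametrize("alpha", [2.0, 5.0, 10.0])
    @pytest.mark.parametrize("hr", [50.0, 100.0])
    def test_round_trip_recovers_alpha_and_csbp(self, alpha, hr):
        p, a = _pressure_wave(alpha=alpha, hr_bpm=hr)
        cal = hd.calibrate_pressure_from_area(a, dbp=70.0, mbp=p.mean())
        assert cal.alpha == pytest.approx(alpha, rel=1e-3)
        assert cal.c_sbp == pytest.approx(p.max(), abs=0.01)
        np.testing.assert_allclose(cal.pressure.values, p.values, atol=0.01)

    def test_mbp_to_dbp_limit_gives_vanishing_pulse(self):
        _, a = _pressure_wave()
        cal = hd.calibrate_pressure_from_area(a, dbp=70.0, mbp=70.0 + 0.05)
        assert cal.alpha < 0.05
        assert cal.c_pp < 0.2
        # below the documented alpha bracket the calibration refuses
        with pytest.raises(ValueError, match="bracket"):
            hd.calibrate_pressure_from_area(a, dbp=70.0, mbp=70.0 + 1e-9)

    def test_central_pulse_pressure_is_sbp_minus_dbp(self):
        _, a = _pressure_wave()
        cal = hd.calibrate_pressure_from_area(a, dbp=70.0, mbp=85.0)
        assert cal.c_pp == pytest.approx(cal.c_sbp - 70.0, abs=1e-12)
        # worked subtraction at the cohort-mean values
        assert 115.0 - 70.0 == 45.0

    def test_pulseless_area_rejected(self):
        a = Waveform(np.full(64, 4.0), 0.01, "cm2")
        with pytest.raises(ValueError, match="pulseless|positive"):
            hd.calibrate_pressure_from_area(a, dbp=70.0, mbp=90.0)


class TestResistance:
    def test_unit_case(self):
        assert hd.vascular_resistance(90.0, 90.0) == 1.0

    def test_doubling_flow_halves_resistance(self):
        assert hd.vascular_resistance(90.0, 160.0) == \
            pytest.approx(hd.vascular_resistance(90.0, 80.0) / 2)

    def test_five_litre_per_minute_case(self):
        # 5 L/min = 83.3 ml/s; R = 93/83.3
        assert hd.vascular_resistance(93.0, 83.3) == pytest.approx(1.116,
                                                                   abs=1e-3)

    def test_zero_flow_rejected(self):
        with pytest.raises(ValueError):
            hd.vascular_resistance(90.0, 0.0)


class TestTotalArterialCompliance:
    def test_sinusoidal_flow_recovers_known_compliance(self):
        n, dt = 128, 0.0075
        t = np.arange(n) * dt
        omega = 2 * np.pi / (n * dt)
        r, c_true = 1.1, 1.2
        flow = Waveform(85 + 45 * np.sin(omega * t), dt, "ml/s")
        target = syn.generate_wk2_pressure(flow, r, c_true).pulse
        c_fit = hd.fit_tac(flow, r, target)
        assert c_fit == pytest.approx(c_true, rel=1e-3)

    def test_smaller_target_needs_larger_compliance(self):
        flow, _, _ = syn.generate_waveforms(syn.WaveGenConfig())
        c1 = hd.fit_tac(flow, 1.1, 50.0)
        c2 = hd.fit_tac(flow, 1.1, 25.0)
        assert c2 > c1

    def test_unattainable_target_rejected(self):
        flow, _, _ = syn.generate_waveforms(syn.WaveGenConfig())
        resistive_limit = 1.1 * flow.pulse
        with pytest.raises(ValueError, match="resistive"):
            hd.fit_tac(flow, 1.1, resistive_limit * 2)

    def test_recovery_across_physiological_grid(self):
        # exact-inverse property over the working range of R, C and rate
        for r in (0.5, 1.2, 2.0):
            for c_true in (0.5, 1.5, 3.0):
                for hr in (50.0, 100.0):
                    period = 60.0 / hr
                    cfg = syn.WaveGenConfig(period=period, dt=period / 100,
                                            onset=0.02, width=0.4 * period,
                                            reflection_delay=0.15 * period)
                    flow, _, _ = syn.generate_waveforms(cfg)
                    target = syn.generate_wk2_pressure(flow, r, c_true).pulse
                    c_fit = hd.fit_tac(flow, r, target)
                    assert abs(c_fit - c_true) / c_true < 5e-3

    def test_taci_is_tac_over_bsa(self, small_cohort):
        _, records, _ = small_cohort
        s = hd.subject_summary(records[0])
        assert s.taci == pytest.approx(s.tac / records[0].bsa, rel=1e-12)


class TestWaveSpeed:
    def test_forward_only_wave_exact(self):
        cfg = syn.WaveGenConfig(reflection_coeff=0.0)
        flow, area, truth = syn.generate_waveforms(cfg)
        c = hd.wave_speed_qa(flow, area)
        assert c == pytest.approx(truth["wave_speed"], rel=1e-12)

    def test_reflection_after_window_small_bias(self):
        cfg = syn.WaveGenConfig(reflection_coeff=0.3, reflection_delay=0.20)
        flow, area, truth = syn.generate_waveforms(cfg)
        c = hd.wave_speed_qa(flow, area)
        assert c == pytest.approx(truth["wave_speed"], rel=0.02)

    def test_flat_area_rejected(self):
        n, dt = 100, 0.0096
        t = np.arange(n) * dt
        flow = Waveform(80 + 40 * np.sin(2 * np.pi * t / (n * dt)), dt, "ml/s")
        area = Waveform(np.full(n, 5.0), dt, "cm2")
        with pytest.raises(ValueError, match="flat|vertical"):
            hd.wave_speed_qa(flow, area)

    def test_scale_equivariance(self):
        cfg = syn.WaveGenConfig(reflection_coeff=0.0)
        flow, area, _ = syn.generate_waveforms(cfg)
        c1 = hd.wave_speed_qa(flow, area)
        area2 = area.with_values(area.values * 2.0)
        c2 = hd.wave_speed_qa(flow, area2)
        assert c2 == pytest.approx(c1 / 2.0, rel=1e-9)


class TestWaveSeparation:
    def test_forward_only_has_no_backward_intensity(self):
        cfg = syn.WaveGenConfig(reflection_coeff=0.0)
        flow, area, truth = syn.generate_waveforms(cfg)
        di_p, di_m, _ = hd.separate_waves_qa(flow, area, truth["wave_speed"])
        assert np.abs(di_m).max() < 1e-10 * di_p.max()

    def test_pure_backward_wave_has_no_forward_intensity(self):
        cfg = syn.WaveGenConfig(reflection_coeff=0.0)
        _, area, truth = syn.generate_waveforms(cfg)
        c = truth["wave_speed"]
        backward_flow = area.with_values(-c * area.values, "ml/s")
        di_p, di_m, _ = hd.separate_waves_qa(backward_flow, area, c)
        assert np.abs(di_p).max() < 1e-10 * np.abs(di_m).max()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           c=st.floats(50.0, 800.0))
    def test_separation_identity_everywhere(self, seed, c):
        rng = np.random.default_rng(seed)
        flow = Waveform(rng.normal(80, 30, 64), 0.01, "ml/s")
        area = Waveform(5 + np.abs(rng.normal(0, 0.5, 64)), 0.01, "cm2")
        di_p, di_m, net = hd.separate_waves_qa(flow, area, c)
        scale = np.abs(net).max() + 1e-30
        np.testing.assert_allclose(di_p + di_m, net, atol=1e-12 * scale)

    def test_gamma_squared_ratio_of_summed_intensities(self):
        cfg = syn.WaveGenConfig(reflection_coeff=0.3, onset=0.02, width=0.30,
                                reflection_delay=0.35, pulse_power=2.0)
        flow, area, truth = syn.generate_waveforms(cfg)
        di_p, di_m, _ = hd.separate_waves_qa(flow, area, truth["wave_speed"])
        ratio = np.abs(di_m).sum() / di_p.sum()
        assert ratio == pytest.approx(0.09, rel=0.05)


class TestWaveAreas:
    def test_null_signal_gives_zero_areas(self):
        cfg = syn.WaveGenConfig(amplitude=0.0)
        flow, area, _ = syn.generate_waveforms(cfg)
        di_p, di_m, _ = hd.separate_waves_qa(flow, area, 400.0)
        assert hd.wave_areas(di_p, di_m) == (0.0, 0.0)

    def test_areas_match_generator_truth(self):
        cfg = syn.WaveGenConfig(reflection_coeff=0.3, onset=0.02, width=0.30,
                                reflection_delay=0.35, pulse_power=2.0)
        flow, area, truth = syn.generate_waveforms(cfg)
        c = hd.wave_speed_qa(flow, area)
        di_p, di_m, _ = hd.separate_waves_qa(flow, area, c)
        fcw, bcw = hd.wave_areas(di_p, di_m)
        assert fcw == pytest.approx(truth["fcw_area"], rel=0.05)
        assert bcw == pytest.approx(truth["bcw_area"], rel=0.05)

    def test_doubling_amplitude_quadruples_fcw(self):
        out = {}
        for amp in (0.3, 0.6):
            cfg = syn.WaveGenConfig(amplitude=amp, reflection_coeff=0.0)
            flow, area, truth = syn.generate_waveforms(cfg)
            di_p, di_m, _ = hd.separate_waves_qa(flow, area,
                                                 truth["wave_speed"])
            out[amp], _ = hd.wave_areas(di_p, di_m)
        assert out[0.6] == pytest.approx(4.0 * out[0.3], rel=1e-6)

    def test_bcw_invariant_to_baseline_offsets(self):
        cfg = syn.WaveGenConfig(reflection_coeff=0.3)
        flow, area, truth = syn.generate_waveforms(cfg)
        c = truth["wave_speed"]
        di = hd.separate_waves_qa(flow, area, c)
        flow2 = flow.with_values(flow.values + 37.0)
        area2 = area.with_values(area.values + 1.5)
        di2 = hd.separate_waves_qa(flow2, area2, c)
        assert hd.wave_areas(*di[:2])[1] == pytest.approx(
            hd.wave_areas(*di2[:2])[1], rel=1e-12)


class TestSubjectSummary:
    def test_full_chain_recovers_generator_truth(self, small_cohort):
        _, records, _ = small_cohort
        for rec in records[:5]:
            s = hd.subject_summary(rec)
            assert s.wave_speed == pytest.approx(rec.truth["wave_speed"],
                                                 rel=0.02)
            assert s.bcw_area / s.fcw_area == pytest.approx(
                rec.truth["gamma"] ** 2, rel=0.05, abs=1e-4)
            assert s.c_pp == pytest.approx(s.c_sbp - rec.dbp, abs=1e-9)
            assert s.taci == pytest.approx(s.tac / rec.bsa, rel=1e-12)
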