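import numpy as np
import pytest

from aopkit import (
    BreathWaveform,
    DetectionConfig,
    LinearCompliance,
    RespiratorySystem,
    SimOptions,
    detect_intrinsic_peep,
    detect_onset,
    fit_slope_break,
    measure_peak_plateau,
    pcond_method,
    simulate_breath,
    simulate_low_flow_maneuver,
    standard_method,
)
from aopkit.mechanics import VentSettings
from aopkit.simulate import vacv_settings


def _waveform(t, flow, paw, fs=100.0):
    return BreathWaveform.from_samples(t, flow, paw, meta={"fs": fs})


class TestOnset:
    def test_square_wave_onset_index(self, cfg):
        t = np.arange(300) / 100.0
        flow = np.where(t >= 1.0, 1.0, 0.0)
        w = _waveform(t, flow, np.full_like(t, 5.0))
        assert detect_onset(w, cfg) == 100

    def test_all_zero_flow_errors(self, cfg):
        t = np.arange(50) / 100.0
        w = _waveform(t, np.zeros_like(t), np.full_like(t, 5.0))
        with pytest.raises(ValueError, match="no insufflation"):
            detect_onset(w, cfg)

    def test_ramped_flow_crossing_threshold(self, cfg):
        # flow ramps linearly, reaching the 2 L/min threshold at t = 0.02 s
        t = np.arange(50) / 100.0
        flow = (2.0 / 60.0) * (t / 0.02)
        w = _waveform(t, flow, np.full_like(t, 5.0))
        # direct-scan oracle
        thr = cfg.onset_flow_threshold / 60.0
        expected = next(i for i in range(len(t) - 2)
                        if all(flow[i + k] >= thr for k in range(3)))
        assert detect_onset(w, cfg) == expected == 2

    def test_brief_spike_is_ignored(self, cfg):
        t = np.arange(100) / 100.0
        flow = np.zeros_like(t)
        flow[10] = 1.0                       # single-sample artifact
        flow[50:] = 1.0
        w = _waveform(t, flow, np.full_like(t, 5.0))
        assert detect_onset(w, cfg) == 50


class TestSlopeBreakFit:
    def test_recovers_piecewise_linear_generator(self, cfg):
        t = np.arange(0, 0.3, 0.01)
        paw = np.where(t < 0.03, 5 + 500 * t, 20 + 12 * (t - 0.03))
        w = _waveform(t, np.full_like(t, 1.0), paw)
        fit = fit_slope_break(w, 0, 0.3, cfg)
        assert fit.p_break == pytest.approx(20.0, abs=0.1)
        assert fit.slope1 == pytest.approx(500.0, rel=0.02)
        assert fit.slope2 == pytest.approx(12.0, rel=0.05)
        assert fit.sse_ratio > 100

    def test_straight_line_has_unit_sse_ratio(self, cfg):
        t = np.arange(0, 0.3, 0.01)
        w = _waveform(t, np.full_like(t, 1.0), 5 + 12 * t)
        fit = fit_slope_break(w, 0, 0.3, cfg)
        assert fit.sse_ratio == pytest.approx(1.0, abs=0.01)

    def test_constant_trace_degenerates_gracefully(self, cfg):
        t = np.arange(0, 0.3, 0.01)
        w = _waveform(t, np.full_like(t, 1.0), np.full_like(t, 8.0))
        fit = fit_slope_break(w, 0, 0.3, cfg)
        assert fit.sse_ratio == pytest.approx(1.0)
        assert fit.slope1 == pytest.approx(0.0, abs=1e-6)
        assert fit.slope2 == pytest.approx(0.0, abs=1e-6)

    def test_window_too_short_errors(self, cfg):
        t = np.arange(0, 0.3, 0.01)
        w = _waveform(t, np.full_like(t, 1.0), 5 + 12 * t)
        with pytest.raises(ValueError, match="need >= 6"):
            fit_slope_break(w, 0, 0.03, cfg)

    def test_noisy_simulated_break_close_to_noise_free(self, bench_circuit,
                                                       scenarios, cfg):
        system, _ = scenarios["aop10"]
        st = vacv_settings(peep=5.0)
        w0 = simulate_breath(system, bench_circuit, st)
        w1 = simulate_breath(system, bench_circuit, st,
                             SimOptions(noise_sd=0.2, seed=1))
        p0 = pcond_method(w0, 5.0, cfg).p_break
        p1 = pcond_method(w1, 5.0, cfg).p_break
        assert p1 == pytest.approx(p0, abs=0.5)


class TestPeakPlateau:
    def test_linear_system_closed_form_values(self, linear_system, small_circuit,
                                              cfg):
        w = simulate_breath(linear_system, small_circuit, vacv_settings(peep=5.0))
        peak, plateau = measure_peak_plateau(w, cfg)
        assert peak == pytest.approx(25.5, abs=0.15)
        assert plateau == pytest.approx(15.5, abs=0.1)
        assert peak - plateau == pytest.approx(10.0, abs=0.2)

    def test_negligible_resistance_peak_equals_plateau(self, small_circuit, cfg):
        s = RespiratorySystem(rrs=0.05, compliance=LinearCompliance(40.0))
        w = simulate_breath(s, small_circuit, vacv_settings(peep=5.0))
        peak, plateau = measure_peak_plateau(w, cfg)
        assert peak - plateau == pytest.approx(0.0, abs=0.1)

    def test_short_pause_errors(self, linear_system, bench_circuit, cfg):
        st = vacv_settings(peep=5.0, pause_s=0.2)
        w = simulate_breath(linear_system, bench_circuit, st)
        with pytest.raises(ValueError, match="occlusion too short"):
            measure_peak_plateau(w, cfg)


class TestPcondMethod:
    def test_bench_closure_recovers_aop(self, bench_circuit, scenarios, cfg):
        system, _ = scenarios["aop10"]
        w = simulate_breath(system, bench_circuit, vacv_settings(peep=5.0))
        res = pcond_method(w, 5.0, cfg)
        assert res.closure_detected
        assert res.aop_reported == 10.0
        # identity AOP = PEEP + (P_cond - P_res) holds exactly before rounding
        assert res.aop == pytest.approx(res.set_peep + res.p_cond - res.p_res)

    def test_peep_above_aop_no_detection(self, bench_circuit, scenarios, cfg):
        system, _ = scenarios["aop10"]
        w = simulate_breath(system, bench_circuit, vacv_settings(peep=12.0))
        res = pcond_method(w, 12.0, cfg)
        assert not res.closure_detected
        assert res.aop is None

    def test_consistency_no_closure_linear(self, linear_system, bench_circuit,
                                           cfg):
        """Without closure, conductive and resistive pressure agree."""
        w = simulate_breath(linear_system, bench_circuit, vacv_settings(peep=5.0))
        res = pcond_method(w, 5.0, cfg)
        assert abs(res.p_cond - res.p_res) < 0.3

    def test_bilinear_control_not_mistaken_for_closure(self, bench_circuit,
                                                       scenarios, cfg):
        """A low inflection point bends the curve mid-insufflation, not at
        onset; the detector must not read it as an opening pressure."""
        system, _ = scenarios["control2"]
        for peep in (5.0, 12.0):
            w = simulate_breath(system, bench_circuit, vacv_settings(peep=peep))
            assert not pcond_method(w, peep, cfg).closure_detected

    def test_threshold_monotonicity(self, bench_circuit, cfg):
        """Raising the closure threshold can only turn detections off."""
        s = RespiratorySystem(rrs=10, compliance=LinearCompliance(40), aop=8)
        w = simulate_breath(s, bench_circuit, vacv_settings(peep=5.0),
                            SimOptions(noise_sd=0.2, seed=5))
        detections = []
        for thr in (0.5, 1.0, 2.0, 3.0, 4.0):
            c = DetectionConfig(closure_threshold=thr)
            detections.append(pcond_method(w, 5.0, c).closure_detected)
        assert detections == sorted(detections, reverse=True)

    def test_break_pressure_tracks_aop(self, bench_circuit, cfg):
        """Raising the opening pressure by d raises the break pressure by d."""
        pbs = []
        for aop in (8.0, 10.0, 12.0, 14.0):
            s = RespiratorySystem(rrs=10, compliance=LinearCompliance(40), aop=aop)
            w = simulate_breath(s, bench_circuit, vacv_settings(peep=5.0))
            pbs.append(pcond_method(w, 5.0, cfg).p_break)
        assert np.diff(pbs) == pytest.approx([2.0, 2.0, 2.0], abs=0.2)

    def test_recovery_across_mechanics(self, bench_circuit, cfg):
        """Pooled recovery within +/-1 cmH2O over a mechanics grid with
        detectable opening pressures (design gate, noise sd 0.2)."""
        ok = total = 0
        for aop in (8.0, 12.0, 16.0):
            for rrs in (5.0, 10.0, 15.0):
                for crs in (20.0, 40.0, 60.0):
                    for seed in range(3):
                        s = RespiratorySystem(
                            rrs=rrs, compliance=LinearCompliance(crs), aop=aop)
                        w = simulate_breath(s, bench_circuit,
                                            vacv_settings(peep=5.0),
                                            SimOptions(noise_sd=0.2, seed=seed))
                        r = pcond_method(w, 5.0, cfg)
                        total += 1
                        ok += bool(r.closure_detected and abs(r.aop - aop) <= 1.0)
        assert ok / total >= 0.9


class TestStandardMethod:
    def test_bench_closure_reads_break_pressure(self, bench_circuit, scenarios,
                                                cfg):
        system, _ = scenarios["aop10"]
        w = simulate_low_flow_maneuver(system, bench_circuit, peep=5.0)
        res = standard_method(w, 5.0, cfg)
        assert res.closure_detected
        assert res.aop_reported == 11.0       # break at ~10.83 cmH2O
        assert res.aop == res.p_break

    @pytest.mark.parametrize("name,peep", [
        ("control1", 5.0), ("control1", 12.0),
        ("control2", 5.0), ("control2", 12.0),
        ("aop10", 12.0),
    ])
    def test_no_closure_cells(self, bench_circuit, scenarios, cfg, name, peep):
        system, _ = scenarios[name]
        w = simulate_low_flow_maneuver(system, bench_circuit, peep=peep)
        assert not standard_method(w, peep, cfg).closure_detected


class TestIntrinsicPeep:
    def test_complete_exhalation_not_flagged(self, linear_system, bench_circuit,
                                             cfg):
        w = simulate_breath(linear_system, bench_circuit, vacv_settings(peep=5.0))
        assert not detect_intrinsic_peep(w, cfg)

    def test_truncated_expiration_flagged(self, bench_circuit, cfg):
        # long time constant (Rrs 15, Crs 60 -> ~1.8 s with the expiratory
        # pathway) against a 2.4 s cycle leaves flow at end-expiration
        s = RespiratorySystem(rrs=15.0, compliance=LinearCompliance(60.0))
        st = VentSettings(insp_flow=60.0, tidal_volume=420.0, peep=5.0,
                          rr=25.0, pause_s=0.4)
        w = simulate_breath(s, bench_circuit, st)
        assert detect_intrinsic_peep(w, cfg)
        assert pcond_method(w, 5.0, cfg).intrinsic_peep_flag

    def test_zero_flow_segment_not_flagged(self, cfg):
        t = np.arange(200) / 100.0
        flow = np.where(t >= 1.0, 1.0, 0.0)
        w = _waveform(t, flow, np.full_like(t, 5.0))
        assert not detect_intrinsic_peep(w, cfg)


class TestConfigValidation:
    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            DetectionConfig(closure_threshold=0.0)

    def test_rejects_short_min_pause(self):
        with pytest.raises(ValueError):
            DetectionConfig(min_pause_s=0.1)

    def test_rejects_unit_slope_ratio(self):
        with pytest.raises(ValueError):
            DetectionConfig(slope_ratio_min=1.0)
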