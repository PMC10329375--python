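import numpy as np
import pytest

from aopkit import (
    LinearCompliance,
    RespiratorySystem,
    SimOptions,
    VentCircuit,
    closed_form_linear,
    simulate_breath,
    simulate_low_flow_maneuver,
)
from aopkit.simulate import low_flow_settings, vacv_settings


class TestClosedFormOracle:
    """The analytic constant-flow solution anchors the numerical simulator."""

    def test_direct_substitution(self, linear_system):
        st = vacv_settings(peep=5.0)
        t = np.array([0.0, 0.2])
        cf = closed_form_linear(linear_system, st, t)
        # paw(0.2) = 5 + 10*1 + 200/40; paw(0+) = peep + Rrs*flow
        assert cf.paw[1] == pytest.approx(20.0)
        assert cf.paw[0] == pytest.approx(15.0)

    def test_simulation_matches_closed_form_in_stiff_limit(self, linear_system,
                                                           small_circuit):
        st = vacv_settings(peep=5.0)
        w = simulate_breath(linear_system, small_circuit, st)
        n = int(st.t_insp * 100)
        cf = closed_form_linear(linear_system, st, w.t[:n])
        # skip the onset sample: the closed form jumps discontinuously there
        assert np.max(np.abs(w.paw[1:n] - cf.paw[1:n])) < 0.05

    def test_rejects_closure_and_bilinear(self, bench_circuit):
        from aopkit import BilinearCompliance
        st = vacv_settings(peep=5.0)
        closed = RespiratorySystem(rrs=10, compliance=LinearCompliance(40), aop=10)
        with pytest.raises(ValueError):
            closed_form_linear(closed, st, np.array([0.0, 0.1]))
        bil = RespiratorySystem(
            rrs=10, compliance=BilinearCompliance(20, 40, 10))
        with pytest.raises(ValueError):
            closed_form_linear(bil, st, np.array([0.0, 0.1]))


class TestSimulateBreath:
    def test_peak_and_plateau_match_equation_of_motion(self, linear_system,
                                                       small_circuit):
        # high output rate so the sampled maximum sits at end-insufflation
        w = simulate_breath(linear_system, small_circuit, vacv_settings(peep=5.0),
                            SimOptions(fs=1000.0))
        st = vacv_settings(peep=5.0)
        n_insp = int(round(st.t_insp * 1000))
        peak = float(w.paw[:n_insp].max())
        assert peak == pytest.approx(5 + 10 * 1.0 + 420 / 40, abs=0.1)
        pause_end = int(round((st.t_insp + st.pause_s) * 1000)) - 1
        assert w.paw[pause_end] == pytest.approx(5 + 420 / 40, abs=0.1)

    def test_volume_conservation(self, bench_circuit, scenarios):
        system, _ = scenarios["aop10"]
        w, internals = simulate_breath(system, bench_circuit,
                                       vacv_settings(peep=5.0),
                                       return_internals=True)
        err = np.abs(internals["v_delivered"]
                     - (internals["v_circuit"] + internals["v_lung"]))
        assert err.max() < 1.0

    def test_volume_column_is_integral_of_flow(self, linear_system, bench_circuit):
        from scipy.integrate import cumulative_trapezoid
        w = simulate_breath(linear_system, bench_circuit, vacv_settings(peep=5.0))
        expected = cumulative_trapezoid(w.flow, w.t, initial=0.0) * 1000.0
        assert np.max(np.abs(w.volume - expected)) < 1.0

    def test_peep_at_or_above_aop_is_identical_to_no_closure(self, bench_circuit):
        closed = RespiratorySystem(rrs=10, compliance=LinearCompliance(40), aop=10)
        open_ = RespiratorySystem(rrs=10, compliance=LinearCompliance(40))
        st = vacv_settings(peep=12.0)
        wa = simulate_breath(closed, bench_circuit, st, SimOptions(seed=3))
        wb = simulate_breath(open_, bench_circuit, st, SimOptions(seed=3))
        assert np.max(np.abs(wa.paw - wb.paw)) < 0.05

    def test_aop_at_or_below_peep_does_not_raise(self, bench_circuit):
        s = RespiratorySystem(rrs=10, compliance=LinearCompliance(40), aop=4.0)
        w = simulate_breath(s, bench_circuit, vacv_settings(peep=5.0))
        assert w.n_samples > 2

    def test_closed_phase_charges_circuit_at_expected_slope(self, bench_circuit):
        s = RespiratorySystem(rrs=10, compliance=LinearCompliance(40), aop=10)
        w = simulate_breath(s, bench_circuit, vacv_settings(peep=5.0))
        # phase A: 1 L/s into 2 mL/cmH2O -> 500 cmH2O/s; first 10 ms span 5->10
        assert (w.paw[1] - w.paw[0]) * w.fs == pytest.approx(500.0, rel=0.01)

    def test_noise_is_seeded_and_on_pressure_only(self, linear_system, bench_circuit):
        st = vacv_settings(peep=5.0)
        w1 = simulate_breath(linear_system, bench_circuit, st,
                             SimOptions(noise_sd=0.3, seed=11))
        w2 = simulate_breath(linear_system, bench_circuit, st,
                             SimOptions(noise_sd=0.3, seed=11))
        w3 = simulate_breath(linear_system, bench_circuit, st,
                             SimOptions(noise_sd=0.3, seed=12))
        assert np.array_equal(w1.paw, w2.paw)
        assert not np.array_equal(w1.paw, w3.paw)
        assert np.array_equal(w1.flow, w3.flow)

    def test_expiration_returns_to_peep(self, linear_system, bench_circuit):
        w = simulate_breath(linear_system, bench_circuit, vacv_settings(peep=5.0))
        assert w.paw[-1] == pytest.approx(5.0, abs=0.1)
        assert abs(w.flow[-1]) * 60 < 2.0


class TestLowFlowManeuver:
    def test_two_slopes_with_break_near_aop(self, bench_circuit, scenarios, cfg):
        from aopkit import detect_onset, fit_slope_break
        system, _ = scenarios["aop10"]
        w = simulate_low_flow_maneuver(system, bench_circuit, peep=5.0)
        onset = detect_onset(w, cfg)
        n_insp = int(5.04 * w.fs)
        fit = fit_slope_break(w, onset, n_insp / w.fs, cfg)
        # break at aop + Rrs*flow ~ 10 + 10*0.083 = 10.83 cmH2O
        assert fit.p_break == pytest.approx(10.83, abs=0.3)
        assert fit.slope1 > 5 * fit.slope2

    def test_no_closure_no_steep_first_slope(self, linear_system, bench_circuit,
                                             cfg):
        from aopkit import standard_method
        w = simulate_low_flow_maneuver(linear_system, bench_circuit, peep=5.0)
        res = standard_method(w, 5.0, cfg)
        assert not res.closure_detected

    def test_gas_trapping_reopens_at_same_pressure(self, bench_circuit):
        """Expiratory re-closure traps alveolar pressure at the AOP, so a
        second simulated breath starts from the same state as the first."""
        s = RespiratorySystem(rrs=10, compliance=LinearCompliance(40), aop=10)
        st = vacv_settings(peep=5.0)
        w1 = simulate_breath(s, bench_circuit, st)
        w2 = simulate_breath(s, bench_circuit, st)
        assert np.array_equal(w1.paw, w2.paw)
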