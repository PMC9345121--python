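"""Peak extraction, current density, G-V / availability curves, Boltzmann fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cav3ephys.gating import steady_state_activation, steady_state_availability
from cav3ephys.protocols import ssi_protocol
from cav3ephys.simulate import Sweep, simulate_recording
from cav3ephys.voltage import (
    CurvePoint,
    build_availability,
    build_gv,
    current_density,
    fit_boltzmann,
    peak_current,
)


def flat_sweep(value=0.0, n=1000, dt=0.1):
    t = (np.arange(n) + 1) * dt
    return Sweep(
        time_ms=t,
        current_pa=np.full(n, value),
        command_mv=np.where(t <= 20, -90.0, -10.0),
        segment_voltages=(-90.0, -10.0),
    )


class TestPeakCurrent:
    def test_flat_zero_trace(self):
        pk = peak_current(flat_sweep(0.0), (20.0, 100.0))
        assert pk.i_peak == 0.0

    def test_baseline_offset_invariance(self, wt):
        rec = simulate_recording(wt, ssi_protocol(), noise_sd=0.0, seed=1)
        sw = rec.sweeps[0]
        shifted = Sweep(
            time_ms=sw.time_ms,
            current_pa=sw.current_pa + 50.0,
            command_mv=sw.command_mv,
            segment_voltages=sw.segment_voltages,
        )
        w = rec.protocol.test_window_ms()
        assert peak_current(shifted, w).i_peak == pytest.approx(
            peak_current(sw, w).i_peak, abs=1e-9
        )

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            peak_current(flat_sweep(), (90.0, 500.0))


class TestCurrentDensity:
    def test_arithmetic(self):
        # |-2084 pA| / 10 pF = 208.4 pA/pF
        from cav3ephys.simulate import Recording
        from cav3ephys.protocols import density_protocol

        proto = density_protocol()
        n = int(140 / 0.1)
        t = (np.arange(n) + 1) * 0.1
        cmd = np.where((t > 20) & (t <= 120), -10.0, -90.0)
        cur = np.where((t > 20) & (t <= 120), -2084.0, 0.0)
        sw = Sweep(time_ms=t, current_pa=cur, command_mv=cmd,
                   segment_voltages=(-90.0, -10.0, -90.0))
        rec = Recording(
            cell_id="c", construct_label="WT", capacitance_pf=10.0, ph=7.4,
            sweeps=(sw,), replicate_batch="b1", hours_post_transfection=24,
            protocol=proto, rng_seed=0,
        )
        assert current_density(rec).density == pytest.approx(208.4, rel=1e-9)

    def test_wt_cohort_mean_hits_published_density(self, wt):
        # conductance calibration targets the cohort-mean density under the
        # default cell-to-cell dispersion
        from cav3ephys.protocols import density_protocol
        from cav3ephys.simulate import generate_cohort

        recs = generate_cohort(wt, density_protocol(), 17, seed=17)
        d = np.array([current_density(r).density for r in recs])
        sem = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 208.4) < 2 * sem

    def test_zero_conductance_zero_density(self):
        from cav3ephys.protocols import density_protocol
        from cav3ephys.simulate import simulate_recording

        from .test_gating import make_params

        rec = simulate_recording(
            make_params(gmax=0.0), density_protocol(), noise_sd=0.0, seed=1
        )
        assert current_density(rec).density == 0.0

    def test_missing_sweep_rejected(self, wt_kinetics_noiseless):
        with pytest.raises(ValueError):
            current_density(wt_kinetics_noiseless)  # 0 mV pulse, not -10


class TestBuildGV:
    def test_matches_activation_curve_shape(self, wt, wt_iv_noiseless):
        # noiseless normalized conductance tracks m_inf up to the common
        # transient correction factor, which cancels in normalization
        pts = {p.voltage: p.value for p in build_gv(wt_iv_noiseless)}
        m = {v: float(steady_state_activation(v, wt)) for v in pts}
        m_max = max(m.values())
        for v in pts:
            if v >= -40:  # above the foot, where both are well resolved
                assert pts[v] == pytest.approx(m[v] / m_max, abs=0.02)

    def test_normalization_max_is_one(self, wt_iv_noiseless):
        values = [p.value for p in build_gv(wt_iv_noiseless)]
        assert max(values) == pytest.approx(1.0)

    def test_reversal_band_excluded(self, wt_iv_noiseless):
        voltages = [p.voltage for p in build_gv(wt_iv_noiseless)]
        assert all(abs(v - 45.0) > 5.0 for v in voltages)


class TestBuildAvailability:
    def test_tracks_h_inf(self, wt, wt_ssi_noiseless):
        # 1-s prepulse >> tau_inact drives h to steady state; the -47.1 mV
        # prepulse leaves half the channels available
        pts = {p.voltage: p.value for p in build_availability(wt_ssi_noiseless)}
        assert pts[-90.0] == pytest.approx(1.0, abs=1e-6)
        assert pts[-45.0] == pytest.approx(
            float(steady_state_availability(-45.0, wt)), abs=0.03
        )
        assert pts[20.0] == pytest.approx(0.0, abs=0.03)


class TestFitBoltzmann:
    def test_exact_logistic_recovery(self):
        pts = [
            CurvePoint(v, float(1 / (1 + np.exp((-20.6 - v) / 5.8))))
            for v in np.arange(-90.0, 65.0, 5.0)
        ]
        fit = fit_boltzmann(pts, "activation")
        assert fit.converged
        assert fit.v05 == pytest.approx(-20.6, abs=1e-6)
        assert fit.slope == pytest.approx(5.8, abs=1e-6)

    @settings(derandomize=True, max_examples=40)
    @given(v05=st.floats(-60, 0), slope=st.floats(2, 15))
    def test_noiseless_recovery_property(self, v05, slope):
        v = np.arange(-90.0, 62.0, 5.0)
        pts = [CurvePoint(x, float(1 / (1 + np.exp((x - v05) / slope)))) for x in v]
        fit = fit_boltzmann(pts, "inactivation")
        assert fit.converged
        assert fit.v05 == pytest.approx(v05, abs=1e-4)
        assert fit.slope == pytest.approx(slope, abs=1e-4)

    def test_voltage_shift_equivariance(self):
        rng = np.random.default_rng(4)
        v = np.arange(-90.0, 62.0, 5.0)
        y = 1 / (1 + np.exp((-25.0 - v) / 7.0)) + rng.normal(0, 0.01, v.size)
        base = fit_boltzmann([CurvePoint(x, yy) for x, yy in zip(v, y)], "activation")
        delta = 13.0
        shifted = fit_boltzmann(
            [CurvePoint(x + delta, yy) for x, yy in zip(v, y)], "activation"
        )
        assert shifted.v05 == pytest.approx(base.v05 + delta, abs=1e-6)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-6)

    def test_degenerate_points_do_not_converge(self):
        pts = [CurvePoint(v, 0.7) for v in range(-90, -40, 10)]
        fit = fit_boltzmann(pts, "activation")
        assert not fit.converged

    def test_wrong_orientation_does_not_converge(self):
        pts = [
            CurvePoint(v, float(1 / (1 + np.exp((v + 47.0) / 7.0))))
            for v in range(-90, 25, 5)
        ]
        fit = fit_boltzmann(pts, "activation")  # decreasing data, activation model
        assert not fit.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann([CurvePoint(0, 0.5)] * 4, "activation")
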