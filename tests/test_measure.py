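"""Peak measurement, rundown/temperature fits, Rs arithmetic, reversal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cavclamp.protocol import build_iv_steps, build_step_step_ramp, sample_waveform
from cavclamp.simcell import ca_cell, simulate_sweep
from cavclamp.measure import (
    bandwidth_from_lag,
    extrapolate_reversal,
    fractional_change,
    lag_from_bandwidth,
    normalized_iv,
    ramp_peak,
    ratio_ramp_step,
    rs_voltage_loss,
    rundown_correct,
    rundown_fit,
    step_peak,
    temperature_regression,
)


@pytest.fixture(scope="module")
def grid(ssr_protocol):
    t, v = sample_waveform(ssr_protocol)
    return t, v


class TestStepPeak:
    def test_parabolic_trough(self, ssr_protocol, grid):
        """A parabola-shaped trough 2 ms into the 0 mV step, depth -2000 pA,
        is located exactly."""
        t, _ = grid
        trace = np.zeros_like(t)
        t0 = 210.0 + 2.0  # pre-roll 10 + segment start 200 + 2 ms
        mask = np.abs(t - t0) <= 1.0
        trace[mask] = -2000.0 * (1.0 - ((t[mask] - t0) / 1.0) ** 2)
        pk = step_peak(trace, ssr_protocol)
        assert pk.value == pytest.approx(-2000.0)
        assert pk.where == pytest.approx(2.0)
        assert pk.flag is None

    def test_monotone_trace_flagged_edge(self, ssr_protocol, grid):
        t, _ = grid
        pk = step_peak(-t.copy(), ssr_protocol)
        assert pk.flag == "edge"

    def test_all_zero_flagged_no_current(self, ssr_protocol, grid):
        t, _ = grid
        pk = step_peak(np.zeros_like(t), ssr_protocol)
        assert pk.value == 0.0
        assert pk.where == 0.5
        assert pk.flag == "no-current"


class TestRampPeak:
    def _trace_with_trough_at(self, grid, v_at):
        t, v = grid
        trace = np.zeros_like(t)
        ramp = (t >= 450.0) & (t <= 550.0)
        trace[ramp] = -500.0 * np.exp(-0.5 * ((v[ramp] - v_at) / 5.0) ** 2)
        return trace

    def test_trough_at_minus2_mV(self, ssr_protocol, grid):
        trace = self._trace_with_trough_at(grid, -2.0)
        pk = ramp_peak(trace, grid[1], ssr_protocol)
        assert pk.where == pytest.approx(-2.0, abs=0.6)

    def test_16mV_hyperpolarizing_shift(self, ssr_protocol, grid):
        """Shifting the trough 16 mV hyperpolarized moves the reported ramp
        voltage from -2 to -18 mV."""
        v0 = ramp_peak(self._trace_with_trough_at(grid, -2.0), grid[1],
                       ssr_protocol).where
        v1 = ramp_peak(self._trace_with_trough_at(grid, -18.0), grid[1],
                       ssr_protocol).where
        assert v1 == pytest.approx(-18.0, abs=0.6)
        assert v1 - v0 == pytest.approx(-16.0, abs=1.2)

    def test_flat_ramp_flagged(self, ssr_protocol, grid):
        pk = ramp_peak(np.zeros_like(grid[0]), grid[1], ssr_protocol)
        assert pk.value == 0.0
        assert pk.flag == "no-current"

    def test_requires_terminal_ramp(self, grid):
        proto = build_iv_steps()[0]
        t, v = sample_waveform(proto)
        with pytest.raises(ValueError):
            ramp_peak(np.zeros_like(t), v, proto)


class TestPeakOracle:
    def test_brute_force_equivalence(self, ssr_protocol, grid):
        """step/ramp peaks equal an exhaustive argmin over the window for
        random traces."""
        t, v = grid
        dt = ssr_protocol.sample_interval
        rng = np.random.default_rng(0)
        s0, s1 = int(round(210.5 / dt)), int(round(250.0 / dt))
        r0, r1 = int(round(450.0 / dt)), int(round(550.0 / dt)) + 1
        for _ in range(100):
            trace = rng.normal(0, 500, len(t))
            pk = step_peak(trace, ssr_protocol)
            k = min(range(s0, s1), key=lambda i: (trace[i], i))
            assert pk.value == trace[k] and pk.where == pytest.approx(k * dt - 210.0)
            rp = ramp_peak(trace, v, ssr_protocol)
            k = min(range(r0, r1), key=lambda i: (trace[i], i))
            assert rp.value == trace[k] and rp.where == v[k]


class TestRatio:
    def test_hand_arithmetic(self):
        assert ratio_ramp_step(-900.0, -300.0) == pytest.approx(1 / 3)

    def test_equal_peaks(self):
        assert ratio_ramp_step(-500.0, -500.0) == 1.0

    def test_zero_step_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ratio_ramp_step(0.0, -100.0)

    @given(st.floats(0.1, 10.0))
    def test_invariant_under_uniform_scaling(self, scale):
        """Scaling the whole trace (what rundown does) leaves the
        ramp-to-step ratio unchanged."""
        assert ratio_ramp_step(-900.0 * scale, -300.0 * scale) == pytest.approx(1 / 3)


class TestRundownFit:
    def test_linear_series_becomes_constant(self):
        amps = 2.0 - 0.005 * np.arange(30)
        fit = rundown_fit(amps)
        corrected = rundown_correct(amps, fit)
        assert np.allclose(corrected, 2.0)

    def test_constant_series_identity(self):
        amps = np.full(20, 1.5)
        fit = rundown_fit(amps)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rundown_correct(amps, fit), amps)

    def test_simulated_rundown_trend_removed(self, ssr_protocol):
        """Correcting a simulated control epoch leaves < 10% of the original
        amplitude trend."""
        from cavclamp import subtract as sub
        from cavclamp.measure import step_peak as speak
        from cavclamp.simcell import Epoch, Schedule, simulate_experiment

        cell = ca_cell(noise_sd=0.0, rundown=(0.15, 120.0, 0.15, 600.0, 0.7))
        exp = simulate_experiment(cell, ssr_protocol,
                                  Schedule((Epoch("control", 0, 30),)), seed=0)
        amps = np.array([
            speak(sub.subtract_passive(sw, ssr_protocol).corrected,
                  ssr_protocol).value
            for sw in exp.sweeps
        ]) / 1e3
        fit = rundown_fit(amps)
        resid = rundown_correct(amps, fit)
        assert abs(rundown_fit(resid).slope) < 0.1 * abs(fit.slope)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            rundown_fit(np.arange(5.0))


class TestTemperatureRegression:
    def test_printed_coefficients_fixture(self):
        """Amplitudes built as 7.299 - 0.295*T are recovered exactly with
        r = -1 (noise-free)."""
        temps = np.linspace(33.0, 39.0, 15)
        amps = 7.299 - 0.295 * temps
        fit = temperature_regression(amps, temps)
        assert fit.slope == pytest.approx(-0.295)
        assert fit.intercept == pytest.approx(7.299)
        assert fit.r == pytest.approx(-1.0)

    def test_null_case(self):
        rng = np.random.default_rng(0)
        temps = np.linspace(33, 39, 40)
        amps = 2.0 + rng.normal(0, 0.05, 40)
        fit = temperature_regression(amps, temps)
        assert abs(fit.r) < 0.4
        assert fit.slope == pytest.approx(0.0, abs=0.02)

    def test_degenerate_temperature_variance(self):
        with pytest.raises(ValueError):
            temperature_regression(np.arange(12.0), np.full(12, 37.0))


class TestReversalExtrapolation:
    def test_printed_ba_coefficients(self):
        # a = 0.794, b = -0.023 -> 34.5, i.e. +35 to the nearest mV
        e = extrapolate_reversal(0.794, -0.023)
        assert round(e) == 35

    def test_unit_case(self):
        assert extrapolate_reversal(1.0, -1.0) == 1.0

    def test_printed_ca_coefficients(self):
        # the Ca2+ pair gives 47.0 by arithmetic
        assert extrapolate_reversal(0.799, -0.017) == pytest.approx(47.0, abs=0.01)

    def test_zero_slope_rejected(self):
        with pytest.raises(ZeroDivisionError):
            extrapolate_reversal(1.0, 0.0)

    @given(st.floats(0.1, 2.0), st.floats(-0.1, -0.001))
    def test_zero_crossing_identity(self, a, b):
        e = extrapolate_reversal(a, b)
        assert a + b * e == pytest.approx(0.0, abs=1e-9)


class TestNormalizedIV:
    def _simulate_peaks(self, e_rev, n_cells=3):
        cells = [ca_cell(noise_sd=0.0, r_s=0.0, cdi_gain=0.0, e_rev=e_rev,
                         act_vhalf=-30.0, act_slope=4.0,
                         rundown=(0.0, 50.0, 0.0, 400.0, 1.0),
                         g_max=60.0 * (1 + 0.2 * i))
                 for i in range(n_cells)]
        rows = []
        for ci, cell in enumerate(cells):
            for proto in build_iv_steps():
                sw, _ = simulate_sweep(cell, proto)
                leak = (sw.v_cmd - cell.e_leak) / cell.r_leak * 1e3
                corr = sw.i_rec - leak
                sl = slice(*[int(round(x / proto.sample_interval))
                             for x in (30.5, 35.0)])
                rows.append({"cell": ci, "v_mV": proto.segments[1].v_start,
                             "peak_pA": corr[sl].min()})
        return pd.DataFrame(rows)

    def test_recovers_reversal_within_2mV(self):
        """On a simulated ohmic channel with E_rev = +35 mV, the linear-limb
        extrapolation lands within 2 mV."""
        fit = normalized_iv(self._simulate_peaks(35.0))
        assert fit.e_rev == pytest.approx(35.0, abs=2.0)

    def test_single_cell_normalization_max_is_one(self):
        peaks = self._simulate_peaks(35.0, n_cells=1)
        m = peaks["peak_pA"].abs() / peaks["peak_pA"].abs().max()
        assert (m == 1.0).sum() == 1

    def test_all_zero_rejected(self):
        df = pd.DataFrame({"cell": [0] * 5, "v_mV": range(5), "peak_pA": [0.0] * 5})
        with pytest.raises(ValueError):
            normalized_iv(df)


class TestRsArithmetic:
    def test_ohms_law_voltage_loss(self):
        assert rs_voltage_loss(2000.0, 5.0) == pytest.approx(10.0)

    def test_zero_peak_zero_loss(self):
        assert rs_voltage_loss(0.0, 5.0) == 0.0

    def test_fractional_change_null(self):
        assert fractional_change(-1500.0, -1500.0) == 0.0

    def test_fractional_change_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            fractional_change(-100.0, 0.0)


class TestLagBandwidth:
    def test_printed_value(self):
        # 1.02 kHz compensation bandwidth corresponds to a 156 us lag
        assert round(lag_from_bandwidth(1020.0)) == 156

    def test_hand_arithmetic(self):
        assert lag_from_bandwidth(159.155) == pytest.approx(1000.0, rel=1e-4)

    @given(st.floats(10.0, 1e4))
    def test_mutual_inverse(self, bw):
        assert bandwidth_from_lag(lag_from_bandwidth(bw)) == pytest.approx(bw)

    @pytest.mark.parametrize("fn", [lag_from_bandwidth, bandwidth_from_lag])
    def test_non_positive_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)
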