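"""Leak (passive) and full-block template subtraction."""

import numpy as np
import pytest

from cavclamp.protocol import sample_waveform
from cavclamp.simcell import (
    Epoch, Schedule, ca_cell, full_blocker, simulate_experiment, simulate_sweep,
    Experiment, Sweep,
)
from cavclamp.subtract import (
    WindowSpec,
    build_block_template,
    choose_method,
    compute_r_input,
    default_windows,
    holding_current,
    passive_trace,
    stability_qc,
    subtract_passive,
    subtract_template,
)

from conftest import NO_RUNDOWN


def _synthetic_sweep(protocol, i_of_v):
    """A hand-built sweep whose current is a pure function of the command."""
    t, v = sample_waveform(protocol)
    return Sweep(0, t, v, i_of_v(v), 37.0, "control", 0.0)


class TestHoldingCurrent:
    def test_constant_trace(self, ssr_protocol):
        sw = _synthetic_sweep(ssr_protocol, lambda v: np.full_like(v, -100.0))
        w = default_windows(ssr_protocol)["minus80"]
        assert holding_current(sw, w, ssr_protocol) == -100.0

    def test_mean_of_linear_trend_is_midpoint(self, ssr_protocol):
        t, v = sample_waveform(ssr_protocol)
        sw = Sweep(0, t, v, np.linspace(0, 100, len(t)), 37.0, "c", 0.0)
        w = WindowSpec(-1, 0.0, 10.0)  # the pre-roll window
        sl = w.sample_slice(ssr_protocol)
        expected = 0.5 * (sw.i_rec[sl.start] + sw.i_rec[sl.stop - 1])
        assert holding_current(sw, w, ssr_protocol) == pytest.approx(expected)

    def test_leak_vanishes_at_its_reversal(self, ssr_protocol):
        cell = ca_cell(g_max=0.0, r_s=0.0, e_leak=-80.0, noise_sd=1.0,
                       rundown=NO_RUNDOWN)
        sw, _ = simulate_sweep(cell, ssr_protocol, rng=0)
        w = default_windows(ssr_protocol)["minus80"]
        assert holding_current(sw, w, ssr_protocol) == pytest.approx(
            0.0, abs=3 * cell.noise_sd / np.sqrt(500)
        )

    def test_window_must_fit_segment(self, ssr_protocol):
        with pytest.raises(ValueError):
            WindowSpec(0, 80.0, 50.0).sample_slice(ssr_protocol)


class TestRInput:
    def test_hand_arithmetic(self, ssr_protocol):
        # I_-90 = -200 pA, I_-80 = -100 pA -> (-10 mV)/(-100 pA) = 100 MOhm
        sw = _synthetic_sweep(
            ssr_protocol, lambda v: np.where(v <= -85.0, -200.0, -100.0)
        )
        w = default_windows(ssr_protocol)
        r = compute_r_input(sw, w["minus90"], w["minus80"], ssr_protocol)
        assert r == pytest.approx(100.0)

    def test_recovers_configured_leak_resistance(self, ssr_protocol, leak_cell):
        cell = leak_cell
        quiet = ca_cell(g_max=0.0, r_s=0.0, noise_sd=0.0, rundown=NO_RUNDOWN)
        sw, _ = simulate_sweep(quiet, ssr_protocol)
        w = default_windows(ssr_protocol)
        r = compute_r_input(sw, w["minus90"], w["minus80"], ssr_protocol)
        assert r == pytest.approx(quiet.r_leak, rel=0.01)

    def test_degenerate_denominator(self, ssr_protocol):
        sw = _synthetic_sweep(ssr_protocol, lambda v: np.full_like(v, -100.0))
        w = default_windows(ssr_protocol)
        with pytest.raises(ZeroDivisionError):
            compute_r_input(sw, w["minus90"], w["minus80"], ssr_protocol)


class TestPassiveTrace:
    def test_anchor_at_minus80(self, ssr_protocol):
        sw = _synthetic_sweep(ssr_protocol, lambda v: np.zeros_like(v))
        pas = passive_trace(sw, r_input=100.0, i_minus80=-100.0)
        assert pas[sw.v_cmd == -80.0][0] == pytest.approx(-100.0)

    def test_hand_arithmetic_at_zero_mV(self, ssr_protocol):
        # I_passive(0 mV) = -100 pA + 80 mV / 100 MOhm = +700 pA
        sw = _synthetic_sweep(ssr_protocol, lambda v: np.zeros_like(v))
        pas = passive_trace(sw, r_input=100.0, i_minus80=-100.0)
        assert pas[sw.v_cmd == 0.0][0] == pytest.approx(700.0)

    def test_reproduces_minus90_window_mean(self, ssr_protocol):
        sw = _synthetic_sweep(
            ssr_protocol, lambda v: np.where(v <= -85.0, -200.0, -100.0)
        )
        w = default_windows(ssr_protocol)
        r = compute_r_input(sw, w["minus90"], w["minus80"], ssr_protocol)
        pas = passive_trace(sw, r, holding_current(sw, w["minus80"], ssr_protocol))
        sl = w["minus90"].sample_slice(ssr_protocol)
        assert np.mean(pas[sl]) == pytest.approx(-200.0)


class TestSubtractPassive:
    def test_exact_on_linear_cell(self, ssr_protocol):
        cell = ca_cell(g_max=0.0, r_s=0.0, noise_sd=0.0, rundown=NO_RUNDOWN)
        sw, _ = simulate_sweep(cell, ssr_protocol)
        res = subtract_passive(sw, ssr_protocol)
        assert np.max(np.abs(res.corrected)) < 1e-6

    def test_reconstruction_identity(self, ssr_protocol, quiet_cell):
        """corrected + passive == recorded, bit for bit."""
        sw, _ = simulate_sweep(quiet_cell, ssr_protocol)
        res = subtract_passive(sw, ssr_protocol)
        pas = sw.i_rec - res.corrected
        assert np.array_equal(res.corrected + pas, sw.i_rec)

    def test_channel_cell_probe_windows_near_zero(self, ssr_protocol, quiet_cell):
        sw, _ = simulate_sweep(quiet_cell, ssr_protocol)
        res = subtract_passive(sw, ssr_protocol)
        w = default_windows(ssr_protocol)
        for key in ("minus90", "minus80"):
            sl = w[key].sample_slice(ssr_protocol)
            assert abs(np.mean(res.corrected[sl])) < 1.0
        # inward peak preserved
        assert res.corrected.min() < -1000.0

    def test_degenerate_sweep_surfaces_error(self, ssr_protocol):
        sw = _synthetic_sweep(ssr_protocol, lambda v: np.full_like(v, -50.0))
        with pytest.raises(ZeroDivisionError):
            subtract_passive(sw, ssr_protocol)


class TestTemplate:
    def test_identical_sweeps_template_equals_input(self, ssr_protocol, quiet_cell):
        sw, _ = simulate_sweep(quiet_cell, ssr_protocol)
        tpl = build_block_template([sw, sw, sw])
        assert np.allclose(tpl, sw.i_rec, rtol=1e-14, atol=0)

    def test_template_is_pointwise_mean(self, ssr_protocol, quiet_cell):
        rng = np.random.default_rng(0)
        sweeps = []
        for i in range(2):
            sw, _ = simulate_sweep(quiet_cell, ssr_protocol, rng=rng, index=i)
            sweeps.append(sw)
        tpl = build_block_template(sweeps)
        assert np.allclose(tpl, 0.5 * (sweeps[0].i_rec + sweeps[1].i_rec))

    def test_template_noise_averages_down(self, ssr_protocol):
        """Five-sweep template sits within ~noise_sd/sqrt(5) of the
        noise-free block trace."""
        cell = ca_cell(noise_sd=4.0, rundown=NO_RUNDOWN)
        rng = np.random.default_rng(1)
        sweeps = [simulate_sweep(cell, ssr_protocol, rng=rng, index=i)[0]
                  for i in range(5)]
        tpl = build_block_template(sweeps)
        resid = tpl - sweeps[0].i_true
        assert np.std(resid) == pytest.approx(cell.noise_sd / np.sqrt(5), rel=0.15)

    def test_subtracting_template_from_itself(self, ssr_protocol, quiet_cell):
        sw, _ = simulate_sweep(quiet_cell, ssr_protocol)
        res = subtract_template(sw, sw.i_rec.copy())
        assert np.all(res.corrected == 0.0)

    def test_length_mismatch(self, ssr_protocol, quiet_cell):
        sw, _ = simulate_sweep(quiet_cell, ssr_protocol)
        with pytest.raises(ValueError):
            subtract_template(sw, sw.i_rec[:-1])

    def test_commutes_with_averaging(self, ssr_protocol):
        cell = ca_cell(rundown=NO_RUNDOWN)
        rng = np.random.default_rng(2)
        sweeps = [simulate_sweep(cell, ssr_protocol, rng=rng, index=i)[0]
                  for i in range(4)]
        tpl = sweeps[0].i_true.copy()
        mean_of_corrected = np.mean(
            [subtract_template(s, tpl).corrected for s in sweeps], axis=0
        )
        mean_sweep = sweeps[0]
        mean_trace = np.mean([s.i_rec for s in sweeps], axis=0)
        corrected_of_mean = mean_trace - tpl
        assert np.allclose(mean_of_corrected, corrected_of_mean)


def _experiment_with(cell, protocol, epochs, seed=0, drug=None):
    return simulate_experiment(cell, protocol, Schedule(tuple(epochs)),
                               seed=seed, drug=drug or full_blocker())


class TestChooseMethod:
    def test_clean_cell_uses_passive_for_ramp(self, ssr_protocol):
        cell = ca_cell(g_out=0.0, rundown=NO_RUNDOWN)
        exp = _experiment_with(cell, ssr_protocol,
                               [Epoch("control", 0, 6), Epoch("block", 100, 6)])
        m = choose_method(exp)
        assert m["step"] == "passive"
        assert m["ramp"] == "passive"
        assert not m["outward"]

    def test_outward_cell_uses_template(self, ssr_protocol):
        cell = ca_cell(g_out=8.0, rundown=NO_RUNDOWN)
        exp = _experiment_with(cell, ssr_protocol,
                               [Epoch("control", 0, 6), Epoch("block", 100, 6)])
        m = choose_method(exp)
        assert m["outward"]
        assert m["ramp"] == "template"
        assert m["template"] is not None

    def test_outward_cell_with_drifting_leak_cannot_isolate(self, ssr_protocol):
        """A leak step change mid-experiment fails stability QC, so the ramp
        cannot be isolated even though a template exists."""
        c1 = ca_cell(g_out=8.0, rundown=NO_RUNDOWN)
        c2 = ca_cell(g_out=8.0, rundown=NO_RUNDOWN, r_leak=150.0)
        e1 = _experiment_with(c1, ssr_protocol, [Epoch("control", 0, 6)])
        e2 = _experiment_with(c2, ssr_protocol,
                              [Epoch("control", 0, 6), Epoch("block", 100, 6)])
        merged = Experiment(c1, e2.drug, ssr_protocol, e2.schedule, 0,
                            e1.sweeps + e2.sweeps)
        m = choose_method(merged)
        assert m["ramp"] == "cannot_isolate"


class TestStabilityQC:
    def test_stable_experiment_no_flags(self, ssr_protocol):
        exp = _experiment_with(ca_cell(rundown=NO_RUNDOWN), ssr_protocol,
                               [Epoch("control", 0, 8)])
        qc = stability_qc(exp)
        assert qc["stable"].all()

    def test_leak_step_change_flagged_from_change_point(self, ssr_protocol):
        a = _experiment_with(ca_cell(rundown=NO_RUNDOWN), ssr_protocol,
                             [Epoch("control", 0, 6)])
        b = _experiment_with(ca_cell(rundown=NO_RUNDOWN, r_leak=150.0),
                             ssr_protocol, [Epoch("control", 0, 4)], seed=1)
        merged = Experiment(a.cell, a.drug, ssr_protocol, a.schedule, 0,
                            a.sweeps + b.sweeps)
        qc = stability_qc(merged)
        assert qc["stable"][:6].all()
        assert not qc["stable"][6:].any()

    def test_single_sweep_rejected(self, ssr_protocol):
        exp = _experiment_with(ca_cell(rundown=NO_RUNDOWN), ssr_protocol,
                               [Epoch("control", 0, 2)])
        exp.sweeps = exp.sweeps[:1]
        with pytest.raises(ValueError):
            stability_qc(exp)
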