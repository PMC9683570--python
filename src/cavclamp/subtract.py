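"""Isolating CaV1.2 current from raw sweeps.

Two offline subtraction methods:

* **Passive (linear leak) subtraction** — per trace, the input resistance is
  computed from the -90 and -80 mV probe windows,
  ``R_input = (V_-90 - V_-80) / (I_-90 - I_-80)``, the linear passive current
  ``I_passive = I_-80 + (V - V_-80) / R_input`` is evaluated at every sample
  of the command waveform, and subtracted.

* **Full-block template subtraction** — several traces recorded under a
  saturating blocker (100 uM verapamil, or high methadone) that fully
  inhibited the ramp current are averaged and subtracted from every trace.
  Used for cells with a nonlinear outward contaminant at positive voltages
  that passive subtraction cannot remove.

The method-selection rule: the *step* current is always quantified from
passive-subtracted traces (a sizable step current remains even under full
block); the *ramp* current uses the template only when the passive-subtracted
full-block trace shows overt outward current in the +30 mV/ramp region AND
the passive membrane properties (R_input, I_-80) are stable over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import VoltageProtocol
from .simcell import Experiment, Sweep

__all__ = [
    "WindowSpec",
    "SubtractionResult",
    "holding_current",
    "compute_r_input",
    "passive_trace",
    "subtract_passive",
    "build_block_template",
    "subtract_template",
    "choose_method",
    "stability_qc",
    "default_windows",
]

#: minimum |I_-90 - I_-80| below which R_input is declared degenerate, pA
DENOMINATOR_FLOOR_PA = 1.0


@dataclass(frozen=True)
class WindowSpec:
    """A measurement window anchored to a protocol segment.

    ``segment`` is the segment index (0-based); ``offset`` ms from segment
    start; ``length`` ms.  ``segment = -1`` anchors to the pre-roll.
    """

    segment: int
    offset: float
    length: float

    def sample_slice(self, protocol: VoltageProtocol) -> slice:
        if self.segment == -1:
            start, end = 0.0, protocol.pre_roll
        else:
            start, end = protocol.segment_bounds()[self.segment]
        w0 = start + self.offset
        w1 = w0 + self.length
        if w1 > end + 1e-9 or w0 < start - 1e-9:
            raise ValueError(
                f"window [{w0}, {w1}] ms does not fit in segment "
                f"{self.segment} [{start}, {end}] ms"
            )
        dt = protocol.sample_interval
        return slice(int(round(w0 / dt)), int(round(w1 / dt)))


def default_windows(protocol: VoltageProtocol) -> dict[str, WindowSpec]:
    """Default probe windows for the step-step-ramp protocol: the final 50 ms
    of the -90 mV segment and of the following -80 mV segment (clear of the
    settling transients at the segment starts)."""
    seg90 = protocol.segment_index(v=-90.0)
    seg80 = seg90 + 1
    d90 = protocol.segments[seg90].duration
    d80 = protocol.segments[seg80].duration
    return {
        "minus90": WindowSpec(seg90, d90 - 50.0, 50.0),
        "minus80": WindowSpec(seg80, d80 - 50.0, 50.0),
    }


@dataclass
class SubtractionResult:
    """Outcome of isolating channel current from one sweep."""

    method: str                     # "passive" | "template"
    corrected: np.ndarray           # pA, same length as the input trace
    r_input: float | None = None    # MOhm (passive method)
    i_minus80: float | None = None  # pA (passive method)
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.method == "passive" and self.r_input is not None and self.r_input <= 0:
            raise ValueError("passive subtraction requires r_input > 0")


def holding_current(sweep: Sweep, window: WindowSpec, protocol: VoltageProtocol) -> float:
    """Mean recorded current (pA) over the window."""
    sl = window.sample_slice(protocol)
    if sl.stop > len(sweep.i_rec):
        raise ValueError("window outside sweep")
    return float(np.mean(sweep.i_rec[sl]))


def _window_voltage(sweep: Sweep, window: WindowSpec, protocol: VoltageProtocol) -> float:
    return float(np.mean(sweep.v_cmd[window.sample_slice(protocol)]))


def compute_r_input(
    sweep: Sweep,
    w_minus90: WindowSpec,
    w_minus80: WindowSpec,
    protocol: VoltageProtocol,
    denominator_floor: float = DENOMINATOR_FLOOR_PA,
) -> float:
    """Input resistance in MOhm from the two probe windows.

    ``(V_-90 - V_-80) / (I_-90 - I_-80)`` with voltages from the command
    trace (mV) and currents as window means (pA); mV/pA = GOhm, so x1000 for
    MOhm.  Raises on a degenerate denominator (|dI| below the floor).
    """
    v90 = _window_voltage(sweep, w_minus90, protocol)
    v80 = _window_voltage(sweep, w_minus80, protocol)
    i90 = holding_current(sweep, w_minus90, protocol)
    i80 = holding_current(sweep, w_minus80, protocol)
    di = i90 - i80
    if abs(di) < denominator_floor:
        raise ZeroDivisionError(
            f"degenerate R_input denominator: |I_-90 - I_-80| = {abs(di):.3g} pA "
            f"< {denominator_floor} pA (sweep {sweep.index})"
        )
    return (v90 - v80) / di * 1e3


def passive_trace(sweep: Sweep, r_input: float, i_minus80: float,
                  v_minus80: float = -80.0) -> np.ndarray:
    """Linear passive current (pA) at every sample of the command waveform:
    ``I_passive = I_-80 + (V - V_-80) / R_input``."""
    if r_input <= 0:
        raise ValueError("r_input must be > 0")
    return i_minus80 + (sweep.v_cmd - v_minus80) / r_input * 1e3


def subtract_passive(
    sweep: Sweep,
    protocol: VoltageProtocol,
    windows: dict[str, WindowSpec] | None = None,
) -> SubtractionResult:
    """Passive-subtract one sweep; R_input is recomputed per trace."""
    if windows is None:
        windows = default_windows(protocol)
    r_in = compute_r_input(sweep, windows["minus90"], windows["minus80"], protocol)
    if r_in <= 0:
        raise ValueError(f"non-physical R_input {r_in:.1f} MOhm (sweep {sweep.index})")
    i80 = holding_current(sweep, windows["minus80"], protocol)
    v80 = _window_voltage(sweep, windows["minus80"], protocol)
    pas = passive_trace(sweep, r_in, i80, v80)
    return SubtractionResult(
        method="passive", corrected=sweep.i_rec - pas, r_input=r_in, i_minus80=i80
    )


def build_block_template(sweeps: list[Sweep]) -> np.ndarray:
    """Pointwise mean of full-block traces (the subtraction template)."""
    if not sweeps:
        raise ValueError("need at least one full-block sweep")
    n = len(sweeps[0].i_rec)
    for s in sweeps:
        if len(s.i_rec) != n or not np.array_equal(s.v_cmd, sweeps[0].v_cmd):
            raise ValueError("template sweeps must share one protocol")
    return np.mean([s.i_rec for s in sweeps], axis=0)


def subtract_template(sweep: Sweep, template: np.ndarray) -> SubtractionResult:
    """Subtract a full-block template from one sweep."""
    if len(template) != len(sweep.i_rec):
        raise ValueError("template length does not match sweep")
    return SubtractionResult(
        method="template", corrected=sweep.i_rec - template, template=template
    )


def stability_qc(
    experiment: Experiment,
    windows: dict[str, WindowSpec] | None = None,
    r_input_frac: float = 0.30,
    i80_abs_pA: float = 50.0,
) -> pd.DataFrame:
    """Flag sweeps whose passive membrane properties drift.

    Per sweep, R_input and I_-80 are compared against the experiment medians;
    a sweep is flagged when R_input deviates by more than ``r_input_frac``
    (fractional) or I_-80 by more than ``i80_abs_pA`` (absolute).  Returns a
    per-sweep table with an overall ``stable`` column.
    """
    if len(experiment.sweeps) < 2:
        raise ValueError("stability QC needs at least 2 sweeps")
    proto = experiment.protocol
    if windows is None:
        windows = default_windows(proto)
    rows = []
    for sw in experiment.sweeps:
        try:
            r_in = compute_r_input(sw, windows["minus90"], windows["minus80"], proto)
        except ZeroDivisionError:
            r_in = np.nan
        rows.append({
            "index": sw.index,
            "r_input_MOhm": r_in,
            "i80_pA": holding_current(sw, windows["minus80"], proto),
        })
    df = pd.DataFrame(rows)
    r_med = df["r_input_MOhm"].median()
    i_med = df["i80_pA"].median()
    df["r_input_flag"] = (
        df["r_input_MOhm"].isna()
        | ((df["r_input_MOhm"] - r_med).abs() > r_input_frac * abs(r_med))
    )
    df["i80_flag"] = (df["i80_pA"] - i_med).abs() > i80_abs_pA
    df["stable"] = ~(df["r_input_flag"] | df["i80_flag"])
    return df


def choose_method(
    experiment: Experiment,
    block_label: str = "block",
    windows: dict[str, WindowSpec] | None = None,
    outward_threshold_pA: float = 50.0,
    sustained_ms: float = 5.0,
    n_template: int = 5,
) -> dict[str, object]:
    """Decide the subtraction method per current region.

    Step current: always passive.  Ramp current: template if and only if the
    passive-subtracted full-block trace exceeds ``outward_threshold_pA``
    (positive, i.e. outward) for at least ``sustained_ms`` anywhere in the
    +30 mV step or ramp region AND the recording passes stability QC;
    passive otherwise.  When a template is required but no full-block epoch
    exists, the ramp is flagged ``"cannot_isolate"``.

    Returns ``{"step": "passive", "ramp": ..., "template": array | None,
    "outward": bool, "stable": bool}``.
    """
    proto = experiment.protocol
    if windows is None:
        windows = default_windows(proto)
    block = [s for s in experiment.sweeps if s.solution == block_label]
    qc = stability_qc(experiment, windows)
    stable = bool(qc["stable"].mean() >= 0.9)

    # outward-contaminant check on the passive-subtracted block trace
    outward = False
    template = None
    if block:
        tail = block[-n_template:]
        template = build_block_template(tail)
        res = subtract_passive(tail[-1], proto, windows)
        bounds = proto.segment_bounds()
        # +30 mV step (second-to-last segment) through the ramp (last)
        t0 = bounds[-2][0]
        dt = proto.sample_interval
        region = res.corrected[int(round(t0 / dt)):]
        above = region > outward_threshold_pA
        need = int(round(sustained_ms / dt))
        run, best = 0, 0
        for a in above:
            run = run + 1 if a else 0
            best = max(best, run)
        outward = best >= need

    if not outward:
        ramp_method = "passive"
    elif template is not None and stable:
        ramp_method = "template"
    elif template is None:
        ramp_method = "cannot_isolate"
    else:
        ramp_method = "cannot_isolate"

    # the "no template available but outward current present" case
    if outward and template is None:
        ramp_method = "cannot_isolate"

    return {
        "step": "passive",
        "ramp": ramp_method,
        "template": template,
        "outward": outward,
        "stable": stable,
        "qc": qc,
    }
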