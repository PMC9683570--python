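"""Per-sweep feature extraction and drift analyses.

Features: the *step peak* (most negative inward current during the 0 mV
step, excluding a short post-transition window), the *ramp peak* (most
negative current over the entire repolarizing ramp) with the command voltage
at which it occurs, and their ratio.  Drift analyses: linear rundown fits and
correction, amplitude-temperature regression, series-resistance voltage-loss
arithmetic (Ohm's law), the compensation lag <-> bandwidth conversion, and
reversal-potential extrapolation from a normalized I-V relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import VoltageProtocol

__all__ = [
    "PeakResult",
    "SweepFeatures",
    "RundownFit",
    "TemperatureFit",
    "IVFit",
    "step_peak",
    "ramp_peak",
    "ratio_ramp_step",
    "features_table",
    "rundown_fit",
    "rundown_correct",
    "temperature_regression",
    "extrapolate_reversal",
    "normalized_iv",
    "rs_voltage_loss",
    "fractional_change",
    "lag_from_bandwidth",
    "bandwidth_from_lag",
]

#: default post-transition exclusion at the 0 mV step, ms (clears the
#: residual capacitive artifact)
STEP_EXCLUSION_MS = 0.5


@dataclass(frozen=True)
class PeakResult:
    value: float          # pA, signed (inward negative)
    where: float          # ms from segment onset (step) or command mV (ramp)
    flag: str | None = None


@dataclass(frozen=True)
class SweepFeatures:
    index: int
    step_peak: float
    step_time_to_peak: float
    ramp_peak: float
    ramp_voltage_at_peak: float
    ratio_ramp_step: float | None


def step_peak(
    corrected: np.ndarray,
    protocol: VoltageProtocol,
    exclusion: float = STEP_EXCLUSION_MS,
    step_v: float = 0.0,
) -> PeakResult:
    """Most negative inward current during the ``step_v`` segment.

    The first ``exclusion`` ms after the transition are excluded; ties break
    to the earliest sample.  Returns the signed peak (pA) and the
    time-to-peak from segment onset (ms).  Flags ``"edge"`` when the minimum
    sits on a window boundary and ``"no-current"`` for an all-zero window.
    """
    seg = protocol.segment_index(v=step_v)
    start, end = protocol.segment_bounds()[seg]
    dt = protocol.sample_interval
    i0 = int(round((start + exclusion) / dt))
    i1 = int(round(end / dt))
    window = corrected[i0:i1]
    if window.size == 0:
        raise ValueError("empty step window")
    k = int(np.argmin(window))
    ttp = (i0 + k) * dt - start
    flag = None
    if np.all(window == 0):
        return PeakResult(0.0, exclusion, "no-current")
    if k == 0 or k == window.size - 1:
        flag = "edge"
    return PeakResult(float(window[k]), ttp, flag)


def ramp_peak(
    corrected: np.ndarray, v_cmd: np.ndarray, protocol: VoltageProtocol
) -> PeakResult:
    """Most negative current over the entire repolarizing ramp.

    Returns the signed peak (pA) and the *command* voltage (mV) at the
    minimizing sample; ties break to the earliest (most depolarized) sample.
    """
    if protocol.segments[-1].kind != "ramp":
        raise ValueError("protocol does not end in a ramp")
    start, end = protocol.segment_bounds()[-1]
    dt = protocol.sample_interval
    i0 = int(round(start / dt))
    i1 = int(round(end / dt)) + 1  # ramp endpoint included
    window = corrected[i0:i1]
    k = int(np.argmin(window))
    flag = "no-current" if np.all(window == 0) else None
    return PeakResult(float(window[k]), float(v_cmd[i0 + k]), flag)


def ratio_ramp_step(step: float, ramp: float) -> float:
    """``ramp_peak / step_peak`` (both signed; positive when both inward)."""
    if step == 0:
        raise ZeroDivisionError("zero step peak")
    return ramp / step


def features_table(
    experiment,
    step_traces: list[np.ndarray],
    ramp_traces: list[np.ndarray],
    subtraction_meta: list[dict] | None = None,
) -> pd.DataFrame:
    """Assemble the one-row-per-sweep features table.

    ``step_traces`` / ``ramp_traces`` are the corrected traces to use for the
    respective regions (they differ when the ramp uses template subtraction).
    """
    proto = experiment.protocol
    rows = []
    for sw, tr_s, tr_r, meta in zip(
        experiment.sweeps, step_traces, ramp_traces,
        subtraction_meta or [{}] * len(experiment.sweeps),
    ):
        sp = step_peak(tr_s, proto)
        rp = ramp_peak(tr_r, sw.v_cmd, proto)
        rows.append({
            "index": sw.index,
            "solution": sw.solution,
            "conc_uM": sw.concentration,
            "step_peak_pA": sp.value,
            "ttp_ms": sp.where,
            "ramp_peak_pA": rp.value,
            "ramp_v_mV": rp.where,
            "ratio": rp.value / sp.value if sp.value != 0 else np.nan,
            "temp_C": sw.temperature,
            **meta,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rundown


@dataclass(frozen=True)
class RundownFit:
    slope: float       # nA per trace
    intercept: float   # nA
    start: int
    stop: int


def rundown_fit(amplitudes: np.ndarray, indices: np.ndarray | None = None,
                min_points: int = 10) -> RundownFit:
    """OLS of amplitude (nA) vs trace index over the given range."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if indices is None:
        indices = np.arange(len(amplitudes))
    indices = np.asarray(indices)
    if len(amplitudes) < min_points:
        raise ValueError(f"rundown fit needs >= {min_points} points")
    res = stats.linregress(indices, amplitudes)
    return RundownFit(float(res.slope), float(res.intercept),
                      int(indices[0]), int(indices[-1]))


def rundown_correct(amplitudes: np.ndarray, fit: RundownFit,
                    indices: np.ndarray | None = None) -> np.ndarray:
    """Add the linearly-lost current back: ``amp - slope * (i - i_start)``.

    A series that is exactly linear in the index becomes constant at its
    range-start value.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if indices is None:
        indices = np.arange(fit.start, fit.start + len(amplitudes))
    return amplitudes - fit.slope * (np.asarray(indices) - fit.start)


# ---------------------------------------------------------------------------
# temperature


@dataclass(frozen=True)
class TemperatureFit:
    slope: float       # nA / degC
    intercept: float   # nA
    r: float           # Pearson correlation


def temperature_regression(amplitudes: np.ndarray, temps: np.ndarray,
                           min_points: int = 10) -> TemperatureFit:
    """OLS of (rundown-corrected) amplitude in nA against bath temperature."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if len(amplitudes) < min_points:
        raise ValueError(f"temperature regression needs >= {min_points} points")
    if np.ptp(temps) < 1.0:
        raise ValueError("temperature range must span >= 1 degC")
    res = stats.linregress(temps, amplitudes)
    return TemperatureFit(float(res.slope), float(res.intercept), float(res.rvalue))


# ---------------------------------------------------------------------------
# reversal potential


@dataclass(frozen=True)
class IVFit:
    a: float           # intercept of normalized current
    b: float           # slope per mV
    e_rev: float       # mV
    v_range: tuple[float, float]


def extrapolate_reversal(a: float, b: float) -> float:
    """Zero crossing of the linear I-V limb ``y = a + b*x``: ``-a / b``."""
    if b == 0:
        raise ZeroDivisionError("zero I-V slope: no reversal")
    return -a / b


def normalized_iv(
    peaks: pd.DataFrame,
    fit_range: tuple[float, float] = (-5.0, 20.0),
) -> IVFit:
    """Normalized I-V relation and extrapolated reversal potential.

    ``peaks`` must have columns ``cell``, ``v_mV``, ``peak_pA`` (one peak per
    cell per test voltage).  Per cell, peaks are normalized to that cell's
    maximum-magnitude current; normalized values are averaged across cells
    per voltage and the linear limb over ``fit_range`` (default -5..+20 mV,
    the Ba2+ range; use -5..+15 for Ca2+) is fit with ``y = a + b*x``.
    """
    if peaks["peak_pA"].abs().max() == 0:
        raise ValueError("no current detected")
    norm = []
    for _, grp in peaks.groupby("cell"):
        m = grp["peak_pA"].abs().max()
        if m == 0:
            continue
        g = grp.copy()
        g["norm"] = g["peak_pA"].abs() / m
        norm.append(g)
    allnorm = pd.concat(norm)
    avg = allnorm.groupby("v_mV")["norm"].mean().reset_index()
    lim = avg[(avg["v_mV"] >= fit_range[0]) & (avg["v_mV"] <= fit_range[1])]
    if len(lim) < 4:
        raise ValueError("need >= 4 test voltages on the linear limb")
    res = stats.linregress(lim["v_mV"], lim["norm"])
    a, b = float(res.intercept), float(res.slope)
    return IVFit(a, b, extrapolate_reversal(a, b), fit_range)


# ---------------------------------------------------------------------------
# series resistance arithmetic


def rs_voltage_loss(i_peak: float, rs_uncompensated: float) -> float:
    """Ohm's-law voltage loss across the uncompensated series resistance, mV.

    |pA| * MOhm = uV, hence the 1e-3.  2000 pA through 5 MOhm -> 10 mV.
    """
    return abs(i_peak) * rs_uncompensated * 1e-3


def fractional_change(i_without: float, i_with: float) -> float:
    """Fractional current loss from not compensating: ``1 - I_off / I_on``."""
    if i_with == 0:
        raise ZeroDivisionError("compensated current is zero")
    return 1.0 - i_without / i_with


def lag_from_bandwidth(bw_hz: float) -> float:
    """Compensation lag (us) equivalent to a feedback bandwidth (Hz):
    ``Lag = 1 / (2*pi*Bandwidth)``; 1.02 kHz -> 156 us."""
    if bw_hz <= 0:
        raise ValueError("bandwidth must be > 0")
    return 1e6 / (2.0 * math.pi * bw_hz)


def bandwidth_from_lag(lag_us: float) -> float:
    """Inverse of :func:`lag_from_bandwidth`."""
    if lag_us <= 0:
        raise ValueError("lag must be > 0")
    return 1e6 / (2.0 * math.pi * lag_us)
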