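"""Command-voltage protocols for whole-cell voltage clamp.

All voltages in this package are *membrane* voltages, i.e. the liquid
junction potential (LJP) is already accounted for.  The only place a
pipette-referenced value appears is :func:`command_for_membrane`, which maps a
desired membrane voltage to the value an experimenter would type into the
amplifier software (``V_pipette = V_membrane + LJP``).

The canonical waveform here is the "step-step-ramp" protocol used to probe
L-type Ca2+ (CaV1.2) current: from a holding potential of -80 mV the cell is
hyperpolarized to -90 mV (passive-leak probe), returned to -80 mV, stepped to
0 mV (eliciting the *step* current, predominantly open-state channels),
further depolarized to +30 mV (driving channels into inactivation), and
finally ramped back down to -80 mV in 100 ms (-1.1 V/s), eliciting the *ramp*
current carried by channels reactivating on repolarization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProtocolSegment",
    "VoltageProtocol",
    "build_step_step_ramp",
    "build_iv_steps",
    "command_for_membrane",
    "sample_waveform",
    "ramp_slope",
]

#: default pre-roll at holding potential prepended to every sampled sweep, ms
PRE_ROLL_MS = 10.0

FORMAT_VERSION = "1.0"


@dataclass(frozen=True)
class ProtocolSegment:
    """One piece of a command waveform.

    kind
        ``"hold"``, ``"step"`` or ``"ramp"``.
    v_start, v_end
        Membrane voltage in mV.  Must be equal unless ``kind == "ramp"``.
    duration
        Segment length in ms, strictly positive.
    """

    kind: str
    v_start: float
    v_end: float
    duration: float

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "step", "ramp"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not self.duration > 0:
            raise ValueError(f"segment duration must be > 0, got {self.duration}")
        if self.kind != "ramp" and self.v_start != self.v_end:
            raise ValueError(
                f"{self.kind} segment must have v_start == v_end "
                f"({self.v_start} != {self.v_end})"
            )


@dataclass(frozen=True)
class VoltageProtocol:
    """An ordered list of contiguous segments from a holding potential.

    holding
        Holding membrane potential, mV (the inter-sweep and pre-roll level).
    segments
        Ordered :class:`ProtocolSegment` list; contiguous in time.
    inter_sweep_interval
        Stimulus repetition interval, s (the protocol is delivered at
        ``1/inter_sweep_interval`` Hz).  Must exceed the total active
        duration.
    ljp
        Liquid junction potential, mV, recorded for provenance; membrane
        voltages in this object are already LJP-corrected.
    sample_interval
        Sampling interval, ms (0.1 ms = 10 kHz default).  Every segment
        duration must be an integer multiple of it, so that segment
        boundaries fall exactly on samples.
    pre_roll
        Holding-level pre-roll prepended to the sampled sweep, ms.  Gives the
        holding-current (I_-80) measurement a home and lets the clamp circuit
        settle before the first segment.
    """

    holding: float = -80.0
    segments: tuple[ProtocolSegment, ...] = ()
    inter_sweep_interval: float = 5.0
    ljp: float = 17.0
    sample_interval: float = 0.1
    pre_roll: float = PRE_ROLL_MS

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        for seg in (*self.segments,):
            n = seg.duration / self.sample_interval
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"segment duration {seg.duration} ms is not an integer "
                    f"multiple of the sample interval {self.sample_interval} ms"
                )
        n = self.pre_roll / self.sample_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("pre_roll must be an integer multiple of sample_interval")
        if self.inter_sweep_interval * 1000.0 <= self.total_duration:
            raise ValueError("inter_sweep_interval must exceed the active duration")

    @property
    def total_duration(self) -> float:
        """Total active (post-pre-roll) duration, ms."""
        return float(sum(s.duration for s in self.segments))

    @property
    def sweep_duration(self) -> float:
        """Pre-roll + active duration, ms."""
        return self.pre_roll + self.total_duration

    def segment_bounds(self) -> list[tuple[float, float]]:
        """(start, end) of each segment in sweep time (pre-roll included), ms."""
        out, t = [], self.pre_roll
        for seg in self.segments:
            out.append((t, t + seg.duration))
            t += seg.duration
        return out

    def segment_index(self, *, kind: str | None = None, v: float | None = None) -> int:
        """Index of the first segment matching ``kind`` and/or voltage ``v``."""
        for i, seg in enumerate(self.segments):
            if kind is not None and seg.kind != kind:
                continue
            if v is not None and seg.v_start != v:
                continue
            return i
        raise ValueError(f"no segment with kind={kind!r}, v={v!r}")

    # --- JSON round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "holding_mV": self.holding,
            "ljp_mV": self.ljp,
            "segments": [
                {
                    "kind": s.kind,
                    "v_start_mV": s.v_start,
                    "v_end_mV": s.v_end,
                    "duration_ms": s.duration,
                }
                for s in self.segments
            ],
            "sample_interval_ms": self.sample_interval,
            "interval_s": self.inter_sweep_interval,
            "pre_roll_ms": self.pre_roll,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        major = str(d.get("format_version", FORMAT_VERSION)).split(".")[0]
        if major != FORMAT_VERSION.split(".")[0]:
            raise ValueError(f"unsupported protocol format version {d['format_version']!r}")
        return cls(
            holding=d["holding_mV"],
            segments=tuple(
                ProtocolSegment(s["kind"], s["v_start_mV"], s["v_end_mV"], s["duration_ms"])
                for s in d["segments"]
            ),
            inter_sweep_interval=d["interval_s"],
            ljp=d["ljp_mV"],
            sample_interval=d["sample_interval_ms"],
            pre_roll=d.get("pre_roll_ms", PRE_ROLL_MS),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "VoltageProtocol":
        return cls.from_dict(json.loads(s))


def build_step_step_ramp(
    *,
    holding: float = -80.0,
    v_probe: float = -90.0,
    t_probe: float = 100.0,
    v_rest: float = -80.0,
    t_rest: float = 100.0,
    v_step: float = 0.0,
    t_step: float = 40.0,
    v_inact: float = 30.0,
    t_inact: float = 200.0,
    v_ramp_end: float = -80.0,
    t_ramp: float = 100.0,
    inter_sweep_interval: float = 5.0,
    ljp: float = 17.0,
    sample_interval: float = 0.1,
) -> VoltageProtocol:
    """The step-step-ramp protocol with the standard segment values.

    Defaults: from -80 mV holding, hyperpolarize to -90 mV for 100 ms,
    repolarize to -80 mV for 100 ms, depolarize to 0 mV for 40 ms, further to
    +30 mV for 200 ms, then ramp down to -80 mV in 100 ms (-1.1 V/s),
    delivered at 5 s intervals (0.2 Hz), sampled at 10 kHz.
    """
    if t_ramp <= 0:
        raise ValueError("ramp of zero duration")
    segs = (
        ProtocolSegment("step", v_probe, v_probe, t_probe),
        ProtocolSegment("step", v_rest, v_rest, t_rest),
        ProtocolSegment("step", v_step, v_step, t_step),
        ProtocolSegment("step", v_inact, v_inact, t_inact),
        ProtocolSegment("ramp", v_inact, v_ramp_end, t_ramp),
    )
    return VoltageProtocol(
        holding=holding,
        segments=segs,
        inter_sweep_interval=inter_sweep_interval,
        ljp=ljp,
        sample_interval=sample_interval,
    )


def build_iv_steps(
    *,
    holding: float = -80.0,
    v_min: float = -80.0,
    v_max: float = 20.0,
    increment: float = 5.0,
    t_step: float = 5.0,
    t_pre: float = 20.0,
    t_post: float = 20.0,
    inter_sweep_interval: float = 5.0,
    ljp: float = 17.0,
    sample_interval: float = 0.1,
) -> list[VoltageProtocol]:
    """Family of brief I-V step protocols, one per test voltage.

    Defaults cover -80 to +20 mV in 5 mV increments (the Ba2+ range; use
    ``v_max=15`` for Ca2+), 5 ms test steps flanked by holding-level steps.
    """
    if increment <= 0:
        raise ValueError("increment must be > 0")
    if v_min >= v_max:
        raise ValueError("empty voltage range (v_min >= v_max)")
    n = int(round((v_max - v_min) / increment)) + 1
    protos = []
    for i in range(n):
        v = v_min + i * increment
        segs = (
            ProtocolSegment("hold", holding, holding, t_pre),
            ProtocolSegment("step", v, v, t_step),
            ProtocolSegment("hold", holding, holding, t_post),
        )
        protos.append(
            VoltageProtocol(
                holding=holding,
                segments=segs,
                inter_sweep_interval=inter_sweep_interval,
                ljp=ljp,
                sample_interval=sample_interval,
            )
        )
    return protos


def command_for_membrane(v_target: float, ljp: float) -> float:
    """Pipette command (mV) that puts the *membrane* at ``v_target``.

    The membrane senses the pipette voltage minus the LJP, so the command is
    ``v_target + ljp`` (e.g. -80 mV membrane with a 17 mV LJP -> -63 mV).
    """
    return v_target + ljp


def sample_waveform(
    protocol: VoltageProtocol, rate: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the membrane-referenced command waveform.

    Parameters
    ----------
    protocol
        The protocol to sample.
    rate
        Samples per ms; defaults to ``1 / protocol.sample_interval``.

    Returns
    -------
    (time, voltage)
        ``time`` in ms starting at 0 (pre-roll included), ``voltage`` in mV.
        Segments are left-closed/right-open: the sample at a step boundary
        takes the *new* segment's voltage.  The final sample (at the end of
        the last segment) takes that segment's end voltage.
    """
    if rate is None:
        rate = 1.0 / protocol.sample_interval
    if rate <= 0:
        raise ValueError("rate must be > 0")
    dt = 1.0 / rate
    total = protocol.sweep_duration
    n = int(round(total / dt))
    t = np.arange(n + 1) * dt
    v = np.full(n + 1, protocol.holding, dtype=float)

    start = protocol.pre_roll
    for seg in protocol.segments:
        end = start + seg.duration
        i0 = int(np.ceil(start / dt - 1e-9))
        i1 = int(np.ceil(end / dt - 1e-9))  # exclusive
        if seg.kind == "ramp":
            frac = (t[i0:i1] - start) / seg.duration
            v[i0:i1] = seg.v_start + (seg.v_end - seg.v_start) * frac
        else:
            v[i0:i1] = seg.v_start
        start = end
    # closing sample at the very end of the last segment
    v[n] = protocol.segments[-1].v_end
    return t, v


def ramp_slope(protocol: VoltageProtocol) -> float:
    """Slope of the final ramp segment in V/s (signed).

    mV/ms equals V/s, so the default protocol's +30 -> -80 mV in 100 ms ramp
    gives -1.1 V/s.
    """
    last = protocol.segments[-1]
    if last.kind != "ramp":
        raise ValueError("protocol does not end in a ramp segment")
    return (last.v_end - last.v_start) / last.duration
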