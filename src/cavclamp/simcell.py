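"""Synthetic whole-cell voltage-clamp recordings of a CaV1.2-expressing cell.

This module is the package's data generator: it produces sweeps with the
statistical and biophysical structure the downstream analysis assumes —
biexponential-plus-plateau current rundown, Q10 temperature scaling,
charge-carrier-dependent inactivation (Ca2+ carries calcium-dependent
inactivation, Ba2+ does not), passive linear leak, an optional nonlinear
outward contaminant at positive voltages, series-resistance voltage error
with partial compensation and a low-pass compensation lag, Gaussian recording
noise, and kinetic state-dependent drug block with facilitation as an
optional phenomenological knob.

Gating is Hodgkin-Huxley style: activation m (current ~ m^2), one
voltage-dependent inactivation gate h, and one calcium-dependent inactivation
gate f driven by a low-pass filter of the instantaneous inward ionic current.
Channel-state occupancies for the binding kinetics are read out as
p_open = m^2*h*f, p_inact = m^2*(1 - h*f), p_rest = 1 - m^2.  The driving
force is ohmic (V - E_rev).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from . import _engine
from .protocol import VoltageProtocol, sample_waveform

__all__ = [
    "CellModel",
    "DrugModel",
    "Epoch",
    "Schedule",
    "Sweep",
    "Experiment",
    "CohortConfig",
    "simulate_sweep",
    "simulate_experiment",
    "make_cohort",
    "equilibrium_block",
    "integrate_binding",
    "state_occupancy",
    "rundown_multiplier",
    "temperature_scale",
    "NO_DRUG",
    "ca_cell",
    "ba_cell",
    "open_inact_blocker",
    "open_blocker",
    "facilitating_blocker",
    "full_blocker",
]

#: internal integration step, ms (sub-sample resolution for ms-scale gates)
DT_INTERNAL_MS = 0.02


@dataclass(frozen=True)
class CellModel:
    """Ground-truth biophysical parameters of one simulated cell.

    Conductances in nS, resistances in MOhm, capacitance in pF, voltages in
    mV, time constants in ms (rundown time constants in s), lag in us.
    ``rundown`` is (a_fast, tau_fast_s, a_slow, tau_slow_s, r_inf) with
    weights summing to 1.
    """

    g_max: float = 70.0
    e_rev: float = 46.0              # +46 mV in external Ca2+, +35 mV in Ba2+
    act_vhalf: float = -18.0
    act_slope: float = 5.0
    tau_act: float = 0.8
    vdi_vhalf: float = -25.0
    vdi_slope: float = 6.0
    tau_vdi: float = 400.0
    cdi_gain: float = 2.5            # 0 for Ba2+ (no CDI)
    tau_cdi: float = 12.0
    r_leak: float = 500.0
    e_leak: float = 0.0
    c_m: float = 35.2
    r_s: float = 4.5
    comp_fraction: float = 0.8
    lag: float = 156.0               # compensation lag, us
    rundown: tuple[float, float, float, float, float] = (0.25, 50.0, 0.40, 400.0, 0.35)
    q10_g: float = 2.3
    q10_rates: float = 2.5
    t_ref: float = 37.0
    g_out: float = 0.0
    out_vhalf: float = 10.0
    out_slope: float = 10.0
    e_out: float = -20.0
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.r_leak <= 0:
            raise ValueError("r_leak must be > 0")
        if self.c_m <= 0:
            raise ValueError("c_m must be > 0")
        if self.r_s < 0:
            raise ValueError("r_s must be >= 0")
        if not 0.0 <= self.comp_fraction <= 1.0:
            raise ValueError("comp_fraction must be in [0, 1]")
        a_f, t_f, a_s, t_s, r_inf = self.rundown
        if abs(a_f + a_s + r_inf - 1.0) > 1e-9:
            raise ValueError("rundown weights must sum to 1")
        if not 0.0 <= r_inf <= 1.0:
            raise ValueError("rundown plateau r_inf must be in [0, 1]")


@dataclass(frozen=True)
class DrugModel:
    """State-dependent binding kinetics of a blocker.

    On-rates in 1/(uM*s) per channel state, off-rate in 1/s.  With all other
    on-rates zero, the equilibrium IC50 against one state is
    ``k_off / k_on_state``.  ``facilitation_gain`` is a phenomenological
    open-state conductance bonus with its own concentration dependence
    (midpoint ``facilitation_ec50``, uM); it makes no mechanistic claim.
    """

    name: str = "drug"
    k_on_open: float = 0.0
    k_on_inact: float = 0.0
    k_on_rest: float = 0.0
    k_off: float = 1.0
    facilitation_gain: float = 0.0
    facilitation_ec50: float = 30.0

    def __post_init__(self) -> None:
        for r in (self.k_on_open, self.k_on_inact, self.k_on_rest, self.k_off):
            if r < 0:
                raise ValueError("binding rates must be >= 0")


NO_DRUG = DrugModel(name="none", k_off=1.0)


@dataclass(frozen=True)
class Epoch:
    """One solution-application epoch of a recording.

    ``temperature`` is either a constant (degC), ``("sin", mean, amp,
    period_sweeps)`` or ``("walk", mean, sd)`` for a per-sweep random walk.
    """

    label: str
    concentration: float = 0.0
    n_sweeps: int = 1
    temperature: float | tuple = 37.0

    def __post_init__(self) -> None:
        if self.n_sweeps <= 0:
            raise ValueError("sweep count must be > 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class Schedule:
    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")

    @property
    def n_sweeps(self) -> int:
        return sum(e.n_sweeps for e in self.epochs)


@dataclass
class Sweep:
    """One recorded stimulus repetition."""

    index: int
    time: np.ndarray           # ms
    v_cmd: np.ndarray          # membrane-referenced command, mV
    i_rec: np.ndarray          # recorded (noisy) current, pA
    temperature: float         # degC
    solution: str
    concentration: float       # uM
    v_m: np.ndarray | None = None      # true membrane voltage (simulator only)
    i_true: np.ndarray | None = None   # pre-noise recorded current (simulator only)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        if len(self.v_cmd) != n or len(self.i_rec) != n:
            raise ValueError("sweep vectors must have equal length")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("sweep time base must be strictly increasing and uniform")


@dataclass
class Experiment:
    """An ordered series of sweeps plus the ground truth that produced it."""

    cell: CellModel
    drug: DrugModel
    protocol: VoltageProtocol
    schedule: Schedule
    seed: int
    sweeps: list[Sweep]
    meta: dict = field(default_factory=dict)


def rundown_multiplier(
    params: tuple[float, float, float, float, float], t: float
) -> float:
    """Conductance multiplier at time ``t`` seconds after break-in.

    Biexponential decay to a plateau: ``a_f*exp(-t/tau_f) + a_s*exp(-t/tau_s)
    + r_inf``; equals 1 at t=0 and r_inf as t -> inf.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    a_f, tau_f, a_s, tau_s, r_inf = params
    return a_f * math.exp(-t / tau_f) + a_s * math.exp(-t / tau_s) + r_inf


def temperature_scale(q10: float, temp: float, t_ref: float) -> float:
    """Standard Q10 factor ``q10 ** ((temp - t_ref) / 10)``."""
    return q10 ** ((temp - t_ref) / 10.0)


def equilibrium_block(
    drug: DrugModel, conc: float, occupancy: tuple[float, float, float]
) -> float:
    """Closed-form unbound channel fraction at fixed state occupancies.

    ``occupancy`` is (p_open, p_inact, p_rest).  Returns
    ``k_off / (k_off + conc * sum(k_on_state * p_state))`` — the oracle the
    time-stepped binding kinetics must converge to.
    """
    po, pi_, pr = occupancy
    if po < 0 or pi_ < 0 or pr < 0 or po + pi_ + pr > 1 + 1e-9:
        raise ValueError("occupancies must be >= 0 and sum to <= 1")
    kon = drug.k_on_open * po + drug.k_on_inact * pi_ + drug.k_on_rest * pr
    if drug.k_off == 0 and (kon == 0 or conc == 0):
        raise ValueError("all rates zero: block undefined")
    return drug.k_off / (drug.k_off + conc * kon)


def integrate_binding(
    drug: DrugModel,
    conc: float,
    occupancy: tuple[float, float, float],
    b0: float,
    duration_s: float,
    dt_s: float = 1e-3,
) -> float:
    """Time-step db/dt at frozen occupancies (RK4); independent route used to
    cross-check :func:`equilibrium_block` and the inter-sweep relaxation."""
    po, pi_, pr = occupancy
    kon = conc * (drug.k_on_open * po + drug.k_on_inact * pi_ + drug.k_on_rest * pr)

    def rhs(b: float) -> float:
        return kon * (1.0 - b) - drug.k_off * b

    b = b0
    n = int(round(duration_s / dt_s))
    for _ in range(n):
        k1 = rhs(b)
        k2 = rhs(b + 0.5 * dt_s * k1)
        k3 = rhs(b + 0.5 * dt_s * k2)
        k4 = rhs(b + dt_s * k3)
        b += dt_s / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return b


def _relax_binding_rest(drug: DrugModel, conc: float, b0: float, duration_s: float) -> float:
    # closed-form first-order relaxation at resting occupancy (p_rest = 1)
    k = conc * drug.k_on_rest + drug.k_off
    if k == 0:
        return b0
    beq = conc * drug.k_on_rest / k
    return beq + (b0 - beq) * math.exp(-k * duration_s)


def _oversample_for(cell: CellModel, sample_interval: float) -> int:
    """Internal RK4 substeps per sample: 20 us by default, refined when the
    clamp circuit's fastest time constant (the partially-compensated
    Rs-membrane pole plus the lag filter) would make 20 us unstable."""
    oversample = max(1, int(round(sample_interval / DT_INTERNAL_MS)))
    if cell.r_s > 0:
        tau_m_ms = cell.r_s * cell.c_m * 1e-3  # MOhm * pF = us
        rate = 1.0 / (tau_m_ms * max(1.0 - cell.comp_fraction, 0.02))
        rate += 1.0 / (cell.lag * 1e-3)
        dt_req = 2.0 / rate  # RK4 real-axis stability bound is ~2.78/rate
        oversample = max(oversample, int(math.ceil(sample_interval / dt_req)))
    return oversample


def _facilitation(drug: DrugModel, conc: float) -> float:
    if drug.facilitation_gain == 0.0 or conc == 0.0:
        return 1.0
    return 1.0 + drug.facilitation_gain * conc / (conc + drug.facilitation_ec50)


def simulate_sweep(
    cell: CellModel,
    protocol: VoltageProtocol,
    conc: float = 0.0,
    drug: DrugModel = NO_DRUG,
    bound_state_in: float = 0.0,
    temp: float = 37.0,
    t_elapsed: float = 0.0,
    rng: np.random.Generator | int | None = None,
    index: int = 0,
    solution: str = "control",
    keep_truth: bool = True,
) -> tuple[Sweep, float]:
    """Simulate one sweep; returns the sweep and the drug-bound fraction at
    its end.

    The clamp circuit is integrated with fixed-step RK4 at 20 us and
    decimated onto the protocol's sample grid.  ``r_s = 0`` is treated as an
    ideal clamp (V_m identical to the command).  ``t_elapsed`` is seconds
    since break-in (sets the rundown multiplier, constant within the sweep);
    ``temp`` scales conductance by q10_g and all gating rates by q10_rates.
    Gaussian noise of sd ``cell.noise_sd`` is added to the recorded current;
    the pre-noise recording is kept in ``sweep.i_true`` when ``keep_truth``.
    """
    if not 0.0 <= bound_state_in <= 1.0:
        raise ValueError("bound_state_in must be in [0, 1]")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    oversample = _oversample_for(cell, protocol.sample_interval)
    dt_int = protocol.sample_interval / oversample
    _, v_int = sample_waveform(protocol, rate=1.0 / dt_int)

    run = rundown_multiplier(cell.rundown, t_elapsed)
    g_eff = cell.g_max * run * temperature_scale(cell.q10_g, temp, cell.t_ref)
    rho = temperature_scale(cell.q10_rates, temp, cell.t_ref)

    i_int, vm_int, b_out, _, _ = _engine.run_clamp(
        v_int, dt_int,
        g_eff, cell.e_rev, cell.act_vhalf, cell.act_slope, cell.tau_act / rho,
        cell.vdi_vhalf, cell.vdi_slope, cell.tau_vdi / rho,
        cell.cdi_gain, cell.tau_cdi / rho,
        1.0 / cell.r_leak, cell.e_leak, cell.c_m,
        cell.r_s, cell.comp_fraction, cell.lag * 1e-3,
        cell.g_out, cell.out_vhalf, cell.out_slope, cell.e_out,
        _facilitation(drug, conc),
        drug.k_on_open, drug.k_on_inact, drug.k_on_rest, drug.k_off,
        conc, bound_state_in,
    )
    if np.isnan(i_int).any():
        t_bad = np.argmax(np.isnan(i_int)) * dt_int
        raise FloatingPointError(
            f"clamp integration diverged at t = {t_bad:.3f} ms "
            f"(sweep {index}, {solution!r})"
        )

    sl = slice(None, None, oversample)
    i_true = i_int[sl].copy()
    v_m = vm_int[sl].copy()
    t = np.arange(i_true.shape[0]) * protocol.sample_interval
    v_cmd = v_int[sl].copy()

    noise = rng.normal(0.0, cell.noise_sd, i_true.shape[0]) if cell.noise_sd > 0 else 0.0
    sweep = Sweep(
        index=index,
        time=t,
        v_cmd=v_cmd,
        i_rec=i_true + noise,
        temperature=temp,
        solution=solution,
        concentration=conc,
        v_m=v_m if keep_truth else None,
        i_true=i_true if keep_truth else None,
    )
    return sweep, float(b_out)


def state_occupancy(
    cell: CellModel,
    protocol: VoltageProtocol,
    temp: float = 37.0,
    include_rest: bool = True,
) -> tuple[float, float, float]:
    """Time-averaged channel-state occupancies (p_open, p_inact, p_rest).

    Averaged over a drug-free sweep, and — with ``include_rest`` — over the
    full stimulus cycle, counting the inter-sweep holding as resting
    occupancy.  In the slow-binding limit these averages plug directly into
    :func:`equilibrium_block` to predict the apparent IC50 of a periodic
    protocol: ``IC50 = k_off / sum(k_on_state * <p_state>)``.
    """
    oversample = _oversample_for(cell, protocol.sample_interval)
    dt_int = protocol.sample_interval / oversample
    _, v_int = sample_waveform(protocol, rate=1.0 / dt_int)
    rho = temperature_scale(cell.q10_rates, temp, cell.t_ref)
    g_eff = cell.g_max * temperature_scale(cell.q10_g, temp, cell.t_ref)
    _, _, _, po, pi_ = _engine.run_clamp(
        v_int, dt_int,
        g_eff, cell.e_rev, cell.act_vhalf, cell.act_slope, cell.tau_act / rho,
        cell.vdi_vhalf, cell.vdi_slope, cell.tau_vdi / rho,
        cell.cdi_gain, cell.tau_cdi / rho,
        1.0 / cell.r_leak, cell.e_leak, cell.c_m,
        cell.r_s, cell.comp_fraction, cell.lag * 1e-3,
        cell.g_out, cell.out_vhalf, cell.out_slope, cell.e_out,
        1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0,
    )
    if include_rest:
        frac = protocol.sweep_duration * 1e-3 / protocol.inter_sweep_interval
        po *= frac
        pi_ *= frac
    return float(po), float(pi_), float(1.0 - po - pi_)


def _epoch_temperature(epoch: Epoch, i: int, rng: np.random.Generator) -> float:
    spec = epoch.temperature
    if isinstance(spec, (int, float)):
        return float(spec)
    kind = spec[0]
    if kind == "sin":
        _, mean, amp, period = spec
        return mean + amp * math.sin(2.0 * math.pi * i / period)
    if kind == "walk":
        _, mean, sd = spec
        # random walk around the mean: cumulative within the epoch
        return mean + float(rng.normal(0.0, sd))
    raise ValueError(f"unknown temperature spec {spec!r}")


def simulate_experiment(
    cell: CellModel,
    protocol: VoltageProtocol,
    schedule: Schedule,
    seed: int,
    drug: DrugModel = NO_DRUG,
    keep_truth: bool = True,
) -> Experiment:
    """Simulate a full recording: the rundown clock, temperature trace and
    drug-bound state carry across sweeps; binding relaxes at resting
    occupancy during the inter-sweep holding.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    sweeps: list[Sweep] = []
    b = 0.0
    idx = 0
    interval = protocol.inter_sweep_interval
    sweep_dur_s = protocol.sweep_duration * 1e-3
    walk = 0.0
    for epoch in schedule.epochs:
        for i in range(epoch.n_sweeps):
            if isinstance(epoch.temperature, tuple) and epoch.temperature[0] == "walk":
                _, mean, sd = epoch.temperature
                walk += float(rng.normal(0.0, sd))
                temp = mean + walk
            else:
                temp = _epoch_temperature(epoch, i, rng)
            sweep, b = simulate_sweep(
                cell, protocol,
                conc=epoch.concentration, drug=drug,
                bound_state_in=b, temp=temp,
                t_elapsed=idx * interval, rng=rng,
                index=idx, solution=epoch.label, keep_truth=keep_truth,
            )
            sweeps.append(sweep)
            b = _relax_binding_rest(drug, epoch.concentration, b, interval - sweep_dur_s)
            idx += 1
    return Experiment(
        cell=cell, drug=drug, protocol=protocol, schedule=schedule,
        seed=seed, sweeps=sweeps,
        meta={"ground_truth": True},
    )


# ---------------------------------------------------------------------------
# presets and cohorts


def ca_cell(**overrides) -> CellModel:
    """Default cell recorded in external Ca2+ (CDI on, E_rev +46 mV)."""
    return replace(CellModel(), **overrides)


def ba_cell(**overrides) -> CellModel:
    """Default cell recorded in external Ba2+ (no CDI, E_rev +35 mV)."""
    base = CellModel(e_rev=35.0, cdi_gain=0.0)
    return replace(base, **overrides)


def open_inact_blocker(name: str = "openinact", **overrides) -> DrugModel:
    """Verapamil-like blocker with affinity for open and inactivated states;
    slow unbinding so block accumulates over 0.2 Hz stimulation."""
    d = DrugModel(name=name, k_on_open=1.0, k_on_inact=2.0, k_on_rest=0.0, k_off=0.1)
    return replace(d, **overrides)


def open_blocker(name: str = "open", **overrides) -> DrugModel:
    """Pure open-state blocker (room-temperature verapamil pattern)."""
    d = DrugModel(name=name, k_on_open=1.5, k_on_inact=0.0, k_on_rest=0.0, k_off=0.1)
    return replace(d, **overrides)


def facilitating_blocker(name: str = "facilitating", **overrides) -> DrugModel:
    """Methadone-like preset: open/inactivated block plus an open-state
    conductance bonus peaking in the tens-of-uM range."""
    d = DrugModel(
        name=name, k_on_open=0.02, k_on_inact=0.05, k_on_rest=0.0, k_off=0.1,
        facilitation_gain=0.6, facilitation_ec50=30.0,
    )
    return replace(d, **overrides)


def full_blocker(name: str = "block", **overrides) -> DrugModel:
    """High-affinity template blocker: at 100 uM block is essentially
    complete (the role verapamil at 100 uM plays in experiments)."""
    d = DrugModel(name=name, k_on_open=20.0, k_on_inact=40.0, k_on_rest=2.0, k_off=0.05)
    return replace(d, **overrides)


@dataclass(frozen=True)
class CohortConfig:
    """How to generate a cohort of cells for a concentration-inhibition study.

    Each cell gets ``conc_per_cell`` (1 or 2) concentrations, assigned round
    robin so every concentration is covered evenly; per-cell lognormal jitter
    (sigma = ``jitter``) is applied to g_max, r_s and the rundown time
    constants.
    """

    n_cells: int = 20
    concentrations: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0)
    conc_per_cell: int = 1
    n_control: int = 15
    n_drug: int = 15
    n_block: int = 0
    block_conc: float = 100.0
    jitter: float = 0.2
    temperature: float = 37.0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if self.conc_per_cell not in (1, 2):
            raise ValueError("conc_per_cell must be 1 or 2")


def make_cohort(
    config: CohortConfig,
    cell: CellModel,
    drug: DrugModel,
    protocol: VoltageProtocol,
    seed: int,
) -> list[Experiment]:
    """Generate a cohort of simulated pharmacology experiments.

    Each experiment's ``meta`` records the jittered ground-truth cell and the
    concentrations assigned; the full manifest is reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    concs = list(config.concentrations)
    experiments = []
    for c_idx in range(config.n_cells):
        jit = lambda: math.exp(rng.normal(0.0, config.jitter)) if config.jitter > 0 else 1.0
        a_f, t_f, a_s, t_s, r_inf = cell.rundown
        cell_i = replace(
            cell,
            g_max=cell.g_max * jit(),
            r_s=cell.r_s * jit(),
            rundown=(a_f, t_f * jit(), a_s, t_s * jit(), r_inf),
        )
        assigned = [concs[(c_idx * config.conc_per_cell + k) % len(concs)]
                    for k in range(config.conc_per_cell)]
        epochs = [Epoch("control", 0.0, config.n_control, config.temperature)]
        for conc in assigned:
            epochs.append(Epoch("drug", conc, config.n_drug, config.temperature))
        if config.n_block > 0:
            epochs.append(Epoch("block", config.block_conc, config.n_block,
                                config.temperature))
        exp = simulate_experiment(
            cell_i, protocol, Schedule(tuple(epochs)),
            seed=int(rng.integers(0, 2**31 - 1)), drug=drug,
        )
        exp.meta.update({
            "cell_id": c_idx,
            "concentrations": assigned,
            "cell_params": asdict(cell_i),
            "drug_params": asdict(drug),
        })
        experiments.append(exp)
    return experiments
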