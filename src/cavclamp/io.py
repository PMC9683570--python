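"""File formats and the report pipeline.

An experiment on disk is a JSON manifest plus sweep data in one of two
dialects: columnar CSV (one file per sweep, columns ``time_ms, v_cmd_mV,
i_pA[, v_m_mV, i_true_pA]``; unknown extra columns are preserved) or a single
HDF5 container with one dataset per sweep.  Both round-trip losslessly.
Files carry a format version; readers reject unknown majors.

Units at the file boundary are frozen: ms, mV, pA, MOhm, pF, uM, degC.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import VoltageProtocol, build_step_step_ramp
from .simcell import (
    CellModel, CohortConfig, DrugModel, Epoch, Experiment, Schedule, Sweep,
    make_cohort, simulate_experiment,
    ba_cell, ca_cell, facilitating_blocker, full_blocker,
    open_blocker, open_inact_blocker, NO_DRUG,
)

__all__ = [
    "FORMAT_VERSION",
    "write_sweeps",
    "read_sweeps",
    "RunConfig",
    "run_pipeline",
    "make_fixtures",
    "config_hash",
]

FORMAT_VERSION = "1.0"

_CORE_COLS = ["time_ms", "v_cmd_mV", "i_pA"]


def _sweep_frame(sw: Sweep) -> pd.DataFrame:
    df = pd.DataFrame({
        "time_ms": sw.time, "v_cmd_mV": sw.v_cmd, "i_pA": sw.i_rec,
    })
    if sw.v_m is not None:
        df["v_m_mV"] = sw.v_m
    if sw.i_true is not None:
        df["i_true_pA"] = sw.i_true
    for k, v in sw.extras.items():
        df[k] = v
    return df


def _frame_sweep(df: pd.DataFrame, meta: dict) -> Sweep:
    extras = {
        c: df[c].to_numpy()
        for c in df.columns
        if c not in (*_CORE_COLS, "v_m_mV", "i_true_pA")
    }
    return Sweep(
        index=meta["index"],
        time=df["time_ms"].to_numpy(),
        v_cmd=df["v_cmd_mV"].to_numpy(),
        i_rec=df["i_pA"].to_numpy(),
        temperature=meta["temp_C"],
        solution=meta["solution"],
        concentration=meta["conc_uM"],
        v_m=df["v_m_mV"].to_numpy() if "v_m_mV" in df else None,
        i_true=df["i_true_pA"].to_numpy() if "i_true_pA" in df else None,
        extras=extras,
    )


def write_sweeps(experiment: Experiment, path: str | Path, dialect: str = "csv") -> Path:
    """Write an experiment (manifest + sweeps) to ``path``; returns the
    manifest path.  ``dialect`` is ``"csv"`` or ``"hdf5"``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sweep_meta = [
        {"index": sw.index, "solution": sw.solution, "conc_uM": sw.concentration,
         "temp_C": sw.temperature}
        for sw in experiment.sweeps
    ]
    manifest = {
        "format_version": FORMAT_VERSION,
        "dialect": dialect,
        "seed": experiment.seed,
        "protocol": experiment.protocol.to_dict(),
        "cell": dataclasses.asdict(experiment.cell),
        "drug": dataclasses.asdict(experiment.drug),
        "schedule": [
            {"label": e.label, "conc_uM": e.concentration, "n_sweeps": e.n_sweeps,
             "temperature": list(e.temperature) if isinstance(e.temperature, tuple)
             else e.temperature}
            for e in experiment.schedule.epochs
        ],
        "sweeps": sweep_meta,
        "meta": {k: v for k, v in experiment.meta.items() if _jsonable(v)},
    }
    if dialect == "csv":
        files = []
        for sw in experiment.sweeps:
            fname = f"sweep_{sw.index:04d}.csv"
            # %.17g round-trips float64 exactly (bit-identical read-back)
            _sweep_frame(sw).to_csv(path / fname, index=False, float_format="%.17g")
            files.append(fname)
        manifest["sweep_files"] = files
    elif dialect == "hdf5":
        import h5py

        h5name = "sweeps.h5"
        with h5py.File(path / h5name, "w") as h5:
            for sw in experiment.sweeps:
                g = h5.create_group(f"sweep_{sw.index:04d}")
                for col, arr in _sweep_frame(sw).items():
                    g.create_dataset(col, data=np.asarray(arr))
        manifest["sweep_container"] = h5name
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    mpath = path / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def read_sweeps(path: str | Path) -> Experiment:
    """Read an experiment written by :func:`write_sweeps` (either dialect)."""
    path = Path(path)
    mpath = path / "manifest.json" if path.is_dir() else path
    manifest = json.loads(mpath.read_text())
    major = str(manifest.get("format_version", "0")).split(".")[0]
    if major != FORMAT_VERSION.split(".")[0]:
        raise ValueError(f"unsupported format version {manifest['format_version']!r}")
    root = mpath.parent
    proto = VoltageProtocol.from_dict(manifest["protocol"])
    cell_d = dict(manifest["cell"])
    cell_d["rundown"] = tuple(cell_d["rundown"])
    cell = CellModel(**cell_d)
    drug = DrugModel(**manifest["drug"])
    schedule = Schedule(tuple(
        Epoch(e["label"], e["conc_uM"], e["n_sweeps"],
              tuple(e["temperature"]) if isinstance(e["temperature"], list)
              else e["temperature"])
        for e in manifest["schedule"]
    ))
    sweeps = []
    if manifest["dialect"] == "csv":
        for meta, fname in zip(manifest["sweeps"], manifest["sweep_files"]):
            fpath = root / fname
            if not fpath.exists():
                raise FileNotFoundError(f"manifest references missing sweep file {fname}")
            df = pd.read_csv(fpath, float_precision="round_trip")
            sweeps.append(_frame_sweep(df, meta))
    else:
        import h5py

        with h5py.File(root / manifest["sweep_container"], "r") as h5:
            for meta in manifest["sweeps"]:
                g = h5[f"sweep_{meta['index']:04d}"]
                df = pd.DataFrame({k: g[k][()] for k in g.keys()})
                sweeps.append(_frame_sweep(df, meta))
    return Experiment(
        cell=cell, drug=drug, protocol=proto, schedule=schedule,
        seed=manifest["seed"], sweeps=sweeps, meta=manifest.get("meta", {}),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# pipeline


_DRUG_PRESETS = {
    "open_inact": open_inact_blocker,
    "open": open_blocker,
    "facilitating": facilitating_blocker,
    "full_block": full_blocker,
}


@dataclasses.dataclass
class RunConfig:
    """Everything a pipeline run needs; the seed is mandatory."""

    seed: int
    carrier: str = "Ca"                   # "Ca" | "Ba"
    drug_preset: str = "open_inact"
    n_cells: int = 6
    concentrations: tuple[float, ...] = (0.3, 1.0, 3.0, 10.0, 30.0)
    n_control: int = 12
    n_drug: int = 12
    jitter: float = 0.2
    temperature: float = 37.0
    out_dir: str = "cavclamp_out"
    make_figures: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "concentrations" in d:
            d["concentrations"] = tuple(d["concentrations"])
        return cls(**d)


def config_hash(config: RunConfig) -> str:
    # hash of the scientific configuration only — output location excluded,
    # so the same run in two directories reports the same provenance
    d = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """simulate -> subtract -> measure -> fit -> report.

    Writes a features table, per-region fit reports, and (optionally)
    concentration-inhibition figures under ``config.out_dir``.  Identical
    config + seed produce byte-identical CSV/JSON outputs.
    """
    from . import subtract as sub
    from .measure import features_table
    from .pharm import ci_bands, end_to_end_ic50

    if config.n_cells <= 0:
        raise ValueError("config with zero cells")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cell = ca_cell() if config.carrier == "Ca" else ba_cell()
    drug = _DRUG_PRESETS[config.drug_preset]()
    protocol = build_step_step_ramp()
    cohort_cfg = CohortConfig(
        n_cells=config.n_cells, concentrations=config.concentrations,
        n_control=config.n_control, n_drug=config.n_drug,
        jitter=config.jitter, temperature=config.temperature,
    )
    cohort = make_cohort(cohort_cfg, cell, drug, protocol, seed=config.seed)

    # features for every cell (passive subtraction for both regions)
    feats = []
    for exp in cohort:
        traces = [sub.subtract_passive(sw, protocol).corrected for sw in exp.sweeps]
        df = features_table(exp, traces, traces)
        df.insert(0, "cell", exp.meta["cell_id"])
        feats.append(df)
    features = pd.concat(feats, ignore_index=True)
    features.to_csv(out / "features.csv", index=False)

    report: dict = {
        "format_version": FORMAT_VERSION,
        "config": {k: v for k, v in config.to_dict().items() if k != "out_dir"},
        "config_hash": config_hash(config),
        "fits": {},
    }
    grid = np.geomspace(min(config.concentrations) / 10,
                        max(config.concentrations) * 10, 50)
    for region in ("step", "ramp"):
        fit, points = end_to_end_ic50(cohort, region=region)
        points.to_csv(out / f"points_{region}.csv", index=False)
        bands = ci_bands(fit, grid)
        bands.to_csv(out / f"ci_{region}.csv", index=False)
        report["fits"][region] = {
            "ic50_uM": fit.ic50, "n_h": fit.n_h, "n_points": fit.n,
            "ssr": fit.ssr, "cov": fit.cov.tolist(),
        }
        if config.make_figures:
            _plot_fit(points, fit, bands, out / f"fit_{region}.png", region)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _plot_fit(points: pd.DataFrame, fit, bands: pd.DataFrame,
              path: Path, region: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ok = points.dropna(subset=["inhibition"]) if "inhibition" in points else points
    ax.semilogx(ok["conc_uM"], ok["inhibition"], "o", mfc="none", color="gray")
    ax.semilogx(bands["conc_uM"], bands["fit"], "-", color="k")
    ax.semilogx(bands["conc_uM"], bands["lower"], "--", color="k", lw=0.8)
    ax.semilogx(bands["conc_uM"], bands["upper"], "--", color="k", lw=0.8)
    ax.set_xlabel("concentration (uM)")
    ax.set_ylabel("fractional inhibition")
    ax.set_title(f"{region}: IC50 {fit.ic50:.2g} uM, nH {fit.n_h:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int = 0) -> dict[str, Experiment]:
    """The five named deterministic fixture experiments used by the tests:
    leak-only, outward-contaminant, rundown, temperature-sweep, and
    facilitation cells."""
    protocol = build_step_step_ramp()
    fixtures: dict[str, Experiment] = {}

    leak_cell = ca_cell(g_max=0.0, r_s=0.0, noise_sd=2.0,
                        rundown=(0.0, 50.0, 0.0, 400.0, 1.0))
    fixtures["leak_only"] = simulate_experiment(
        leak_cell, protocol, Schedule((Epoch("control", 0.0, 5),)), seed=seed,
    )

    outward_cell = ca_cell(g_out=8.0, rundown=(0.0, 50.0, 0.0, 400.0, 1.0))
    sched = Schedule((Epoch("control", 0.0, 12), Epoch("block", 100.0, 6)))
    fixtures["outward"] = simulate_experiment(
        outward_cell, protocol, sched, seed=seed + 1, drug=full_blocker(),
    )

    fixtures["rundown"] = simulate_experiment(
        ca_cell(), protocol, Schedule((Epoch("control", 0.0, 40),)), seed=seed + 2,
    )

    temp_cell = ca_cell(rundown=(0.0, 50.0, 0.0, 400.0, 1.0))
    fixtures["temperature"] = simulate_experiment(
        temp_cell, protocol,
        Schedule((Epoch("control", 0.0, 24, ("sin", 35.5, 3.0, 24.0)),)),
        seed=seed + 3,
    )

    fixtures["facilitation"] = simulate_experiment(
        ca_cell(), protocol,
        Schedule((Epoch("control", 0.0, 12), Epoch("drug", 30.0, 12))),
        seed=seed + 4, drug=facilitating_blocker(),
    )
    return fixtures
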