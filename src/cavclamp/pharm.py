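"""Concentration-inhibition analysis: fractional inhibition, Hill fits with
95% confidence bands, and cross-condition potency ratios.

Fractional inhibition per cell is ``1 - I_drug / I_control`` where each side
is the mean of the last 10 traces of its epoch; negative values (current
facilitation) are legal and preserved.  Individual cells' points — not
concentration means — are fit with the Hill equation

    inhibition = 1 / (1 + (IC50 / [drug])^n_H)

by bounded trust-region nonlinear least squares parameterized in
``log10(IC50)``, multi-started across the tested concentration range.
Confidence bands are first-order (delta-method) propagation of the parameter
covariance, with a seeded cell-level bootstrap available as an option.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ConcResponsePoint",
    "HillFit",
    "PotencyComparison",
    "fractional_inhibition",
    "hill_eval",
    "fit_hill",
    "ci_bands",
    "potency_ratio",
    "compare_conditions",
    "end_to_end_ic50",
    "bootstrap_ci_bands",
]

LN10 = math.log(10.0)
NH_BOUNDS = (0.05, 5.0)


@dataclass(frozen=True)
class ConcResponsePoint:
    cell: object
    concentration: float          # uM, > 0
    inhibition: float             # <= 1; negative = facilitation
    region: str = "step"          # "step" | "ramp"
    carrier: str = "Ca"
    temperature_class: str = "nearPT"

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.inhibition > 1:
            raise ValueError("inhibition cannot exceed 1")


@dataclass
class HillFit:
    ic50: float                   # uM
    n_h: float
    cov: np.ndarray               # 2x2 in (log10 ic50, n_h)
    n: int
    ssr: float
    success: bool = True
    message: str = ""
    cov_ok: bool = True

    @property
    def log_ic50(self) -> float:
        return math.log10(self.ic50)


@dataclass(frozen=True)
class PotencyComparison:
    label_a: str
    label_b: str
    ic50_a: float
    ic50_b: float
    ratio: float                  # max-to-min, >= 1


def fractional_inhibition(
    control: np.ndarray, drug: np.ndarray, k: int = 10, strict: bool = True
) -> float:
    """``1 - mean(last k drug) / mean(last k control)``.

    With ``strict`` (default) both series must hold at least ``k`` entries;
    otherwise whatever is available is used.  Negative results (facilitation)
    are returned as-is.
    """
    control = np.asarray(control, dtype=float)
    drug = np.asarray(drug, dtype=float)
    if strict and (len(control) < k or len(drug) < k):
        raise ValueError(f"need >= {k} traces in each epoch "
                         f"(got {len(control)} control, {len(drug)} drug)")
    c = control[-k:].mean()
    d = drug[-k:].mean()
    if c == 0:
        raise ZeroDivisionError("zero control mean")
    return 1.0 - d / c


def hill_eval(ic50: float, n_h: float, conc) -> np.ndarray | float:
    """Hill inhibition ``1 / (1 + (IC50/conc)^n_H)``; 0.5 at conc == IC50,
    strictly increasing in concentration."""
    conc = np.asarray(conc, dtype=float)
    out = 1.0 / (1.0 + (ic50 / conc) ** n_h)
    return float(out) if out.ndim == 0 else out


def _residuals(x: np.ndarray, logc: np.ndarray, y: np.ndarray) -> np.ndarray:
    p, nh = x
    u = nh * LN10 * (p - logc)
    # sigmoid(-u), numerically safe
    pred = np.where(u > 0, np.exp(-u) / (1.0 + np.exp(-u)), 1.0 / (1.0 + np.exp(u)))
    return pred - y


def fit_hill(
    concentrations: np.ndarray,
    inhibitions: np.ndarray,
    drop_negative_concs: bool = False,
) -> HillFit:
    """Fit the Hill equation to individual concentration-inhibition points.

    Requires >= 3 points at >= 2 distinct concentrations.  Parameterized in
    ``log10(IC50)`` with ``n_H`` bounded to (0.05, 5]; three deterministic
    starts span the tested concentration range, and the best converged
    solution wins.  With ``drop_negative_concs`` (the facilitation rule),
    concentrations whose *mean* inhibition is negative are excluded before
    fitting.

    The covariance is the Gauss-Newton estimate ``s^2 (J'J)^-1`` in
    (log10 IC50, n_H) space.
    """
    conc = np.asarray(concentrations, dtype=float)
    inh = np.asarray(inhibitions, dtype=float)
    if conc.shape != inh.shape:
        raise ValueError("concentration / inhibition length mismatch")
    if drop_negative_concs:
        keep = np.ones_like(conc, dtype=bool)
        for c in np.unique(conc):
            if inh[conc == c].mean() < 0:
                keep &= conc != c
        conc, inh = conc[keep], inh[keep]
    if len(np.unique(conc)) < 2:
        raise ValueError("Hill fit needs >= 2 distinct concentrations")
    if len(conc) < 3:
        raise ValueError("Hill fit needs >= 3 points")

    logc = np.log10(conc)
    lo, hi = logc.min(), logc.max()
    starts = [(lo, 1.0), (0.5 * (lo + hi), 1.0), (hi, 1.0)]
    bounds = ([lo - 4.0, NH_BOUNDS[0]], [hi + 4.0, NH_BOUNDS[1]])

    best = None
    for x0 in starts:
        sol = optimize.least_squares(
            _residuals, x0=np.array(x0), bounds=bounds, args=(logc, inh),
            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(
            f"Hill fit did not converge: {getattr(best, 'message', 'no solution')}"
        )

    p, nh = best.x
    n = len(conc)
    ssr = 2.0 * best.cost
    dof = max(n - 2, 1)
    J = best.jac
    JTJ = J.T @ J
    cov_ok = True
    try:
        cov = np.linalg.inv(JTJ) * (ssr / dof)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
        cov_ok = False
    return HillFit(
        ic50=10.0 ** p, n_h=float(nh), cov=cov, n=n, ssr=float(ssr),
        success=True, message=best.message, cov_ok=cov_ok,
    )


def ci_bands(fit: HillFit, grid: np.ndarray, level: float = 0.95) -> pd.DataFrame:
    """Pointwise confidence bands for the fitted inhibition curve.

    Delta method: the gradient of the Hill curve w.r.t. (log10 IC50, n_H) is
    propagated through the parameter covariance; the half-width uses the
    Student-t quantile at ``n - 2`` degrees of freedom.  Bands always contain
    the fitted curve.  A singular covariance flags the bands unreliable
    (NaN half-widths).
    """
    grid = np.asarray(grid, dtype=float)
    pred = hill_eval(fit.ic50, fit.n_h, grid)
    if not fit.cov_ok or not np.all(np.isfinite(fit.cov)):
        half = np.full_like(grid, np.nan)
    else:
        logc = np.log10(grid)
        p = fit.log_ic50
        f = np.asarray(pred)
        d_dp = -f * (1.0 - f) * fit.n_h * LN10
        d_dnh = -f * (1.0 - f) * LN10 * (p - logc)
        G = np.stack([d_dp, d_dnh], axis=1)
        var = np.einsum("ij,jk,ik->i", G, fit.cov, G)
        var = np.clip(var, 0.0, None)
        dof = max(fit.n - 2, 1)
        q = stats.t.ppf(0.5 + level / 2.0, dof)
        half = q * np.sqrt(var)
    return pd.DataFrame({
        "conc_uM": grid,
        "fit": np.asarray(pred),
        "lower": np.asarray(pred) - half,
        "upper": np.asarray(pred) + half,
    })


def bootstrap_ci_bands(
    concentrations: np.ndarray,
    inhibitions: np.ndarray,
    cells: np.ndarray,
    grid: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Nonparametric cell-level bootstrap alternative to :func:`ci_bands`.

    Cells (not points) are resampled with replacement; each replicate is
    refit and the pointwise percentile envelope of the replicate curves is
    reported.  Seeded and deterministic.
    """
    conc = np.asarray(concentrations, dtype=float)
    inh = np.asarray(inhibitions, dtype=float)
    cells = np.asarray(cells)
    grid = np.asarray(grid, dtype=float)
    uniq = np.unique(cells)
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_boot):
        pick = rng.choice(uniq, size=len(uniq), replace=True)
        idx = np.concatenate([np.flatnonzero(cells == c) for c in pick])
        try:
            fit = fit_hill(conc[idx], inh[idx])
        except (ValueError, RuntimeError):
            continue
        curves.append(hill_eval(fit.ic50, fit.n_h, grid))
    if not curves:
        raise RuntimeError("no bootstrap replicate converged")
    arr = np.vstack(curves)
    alpha = (1.0 - level) / 2.0
    fit0 = fit_hill(conc, inh)
    return pd.DataFrame({
        "conc_uM": grid,
        "fit": np.asarray(hill_eval(fit0.ic50, fit0.n_h, grid)),
        "lower": np.quantile(arr, alpha, axis=0),
        "upper": np.quantile(arr, 1.0 - alpha, axis=0),
    })


def potency_ratio(ic50_a: float, ic50_b: float,
                  label_a: str = "a", label_b: str = "b") -> PotencyComparison:
    """Max-to-min ratio of an IC50 pair (>= 1 by construction)."""
    if ic50_a <= 0 or ic50_b <= 0:
        raise ValueError("IC50s must be > 0")
    return PotencyComparison(
        label_a, label_b, ic50_a, ic50_b,
        max(ic50_a, ic50_b) / min(ic50_a, ic50_b),
    )


def compare_conditions(fits: dict[str, HillFit | float]) -> pd.DataFrame:
    """All pairwise max-to-min IC50 ratios across labelled conditions."""
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    vals = {k: (v.ic50 if isinstance(v, HillFit) else float(v))
            for k, v in fits.items()}
    rows = []
    for (ka, va), (kb, vb) in itertools.combinations(vals.items(), 2):
        pc = potency_ratio(va, vb, ka, kb)
        rows.append({
            "label_a": ka, "label_b": kb,
            "ic50_a_uM": va, "ic50_b_uM": vb, "ratio": pc.ratio,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline


def end_to_end_ic50(
    cohort: list,
    region: str = "step",
    k: int = 10,
    drop_negative_concs: bool = True,
    strict: bool = True,
) -> tuple[HillFit, pd.DataFrame]:
    """Run the full analysis on a simulated cohort and fit one Hill curve.

    Per experiment: stability QC and method selection, passive (and, where
    required, template) subtraction, step/ramp peak measurement, fractional
    inhibition per drug epoch against the control epoch, then a Hill fit on
    the pooled individual-cell points.  Returns the fit and the per-cell
    points table (with method/QC provenance columns).
    """
    from . import subtract as sub
    from .measure import ramp_peak, step_peak

    if region not in ("step", "ramp"):
        raise ValueError("region must be 'step' or 'ramp'")
    rows = []
    for exp in cohort:
        proto = exp.protocol
        method = sub.choose_method(exp)
        if region == "ramp" and method["ramp"] == "cannot_isolate":
            rows.append({"cell": exp.meta.get("cell_id"), "error": "cannot_isolate"})
            continue
        use_template = region == "ramp" and method["ramp"] == "template"
        amps: dict[tuple[str, float], list[float]] = {}
        order: list[tuple[str, float]] = []
        for sw in exp.sweeps:
            key = (sw.solution, sw.concentration)
            if key not in amps:
                amps[key] = []
                order.append(key)
            if use_template:
                res = sub.subtract_template(sw, method["template"])
            else:
                res = sub.subtract_passive(sw, proto)
            if region == "step":
                amps[key].append(step_peak(res.corrected, proto).value)
            else:
                amps[key].append(ramp_peak(res.corrected, sw.v_cmd, proto).value)
        ctrl_key = order[0]
        for key in order[1:]:
            label, conc = key
            if label == "block" or conc <= 0:
                continue
            try:
                fi = fractional_inhibition(
                    np.array(amps[ctrl_key]), np.array(amps[key]), k=k, strict=strict
                )
            except (ValueError, ZeroDivisionError) as err:
                rows.append({"cell": exp.meta.get("cell_id"),
                             "conc_uM": conc, "error": str(err)})
                continue
            rows.append({
                "cell": exp.meta.get("cell_id"),
                "conc_uM": conc,
                "inhibition": fi,
                "region": region,
                "method": "template" if use_template else "passive",
                "stable": method["stable"],
            })
    points = pd.DataFrame(rows)
    ok = points.dropna(subset=["inhibition"]) if "inhibition" in points else points.iloc[0:0]
    if len(ok) < 3:
        raise ValueError(f"too few usable points for a Hill fit ({len(ok)})")
    fit = fit_hill(ok["conc_uM"].to_numpy(), ok["inhibition"].to_numpy(),
                   drop_negative_concs=drop_negative_concs)
    return fit, points
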