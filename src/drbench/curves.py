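"""Replicate-aware dose-response preprocessing and 4PL curve fitting.

Raw viability screens arrive as long tables of (cell line, drug, replicate,
dose, signal, control signal).  Signals are normalized per replicate by the
replicate's own no-drug control; replicates are then pooled and a single
four-parameter log-logistic curve

    v(x) = back + (front − back) / (1 + 10^(slope · (x − log10 EC50)))

is fitted jointly over all replicate points of one drug–cell-line pair
(x = log10 dose in µM).  Fitting across replicates, rather than averaging
first, lets replicate scatter enter the residuals and hence the curve's
significance measure: an F-test of the sigmoid against the flat
constant-mean model.  Positive ``slope`` means viability decreases with
dose.  Derived measures: pEC50 = −log10(EC50 [µM]), absolute IC50 (dose at
which the fitted curve crosses viability 0.5), its natural log, and AUC (mean
fitted viability over the dosed log-range; lower = more sensitive).

Validity rules mirror common screen QC: an EC50 outside the dosed range is
flagged invalid, and an IC50 more than one order of magnitude outside the
dosed range ([dmin/10, dmax·10]) is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

VIABILITY_COLUMNS = ("cell_line_id", "drug_id", "replicate_id", "dose", "signal", "control_signal")

#: Offset added to pEC50 when reporting on the molar scale (µM = 1e-6 M).
MOLAR_PEC50_OFFSET = 6.0

_N_STARTS = 5
_AUC_GRID = 2001


@dataclass
class FittedCurve:
    """Fitted 4PL parameters plus derived response measures and QC flags."""

    front: float
    back: float
    slope: float
    pec50: float  # −log10(EC50 [µM])
    p_value: float
    ec50: float  # µM
    ic50: float | None = None  # µM
    ln_ic50: float | None = None
    auc: float | None = None
    ec50_valid: bool = True
    converged: bool = True
    rss: float = float("nan")
    n_points: int = 0

    def viability(self, log10_dose) -> np.ndarray:
        """Fitted viability at the given log10 dose(s)."""
        return four_pl(np.asarray(log10_dose, dtype=float), self.front, self.back, self.slope, -self.pec50)


def four_pl(x: np.ndarray, front: float, back: float, slope: float, log_ec50: float) -> np.ndarray:
    """Four-parameter log-logistic viability curve in log10-dose space."""
    z = np.clip(slope * (x - log_ec50), -300, 300)
    return back + (front - back) / (1.0 + 10.0**z)


def normalize_viability(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``viability`` column: signal / same-replicate control signal.

    Values above 1 (growth stimulation) are retained, not clipped.
    """
    missing = [c for c in VIABILITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"viability table missing column(s): {', '.join(missing)}")
    bad = table["control_signal"] <= 0
    if bad.any():
        row = table.loc[bad].iloc[0]
        raise ValueError(
            f"non-positive control signal for replicate {row['replicate_id']!r} "
            f"of pair ({row['cell_line_id']!r}, {row['drug_id']!r})"
        )
    if (table["dose"] <= 0).any():
        raise ValueError("doses must be strictly positive (µM)")
    out = table.copy()
    out["viability"] = out["signal"] / out["control_signal"]
    return out


_LN10 = np.log(10.0)


def _fit_least_squares(x, v, fix_front):
    """Multi-start bounded least squares; returns (params, rss, converged)."""
    v_lo, v_hi = float(np.min(v)), float(np.max(v))
    quantiles = np.quantile(np.unique(x), [0.15, 0.35, 0.5, 0.65, 0.85])
    rng = np.random.default_rng(20240501)  # start jitter only; data-independent
    spread = max(v_hi - v_lo, 1e-3)

    def _parts(front, back, slope, m):
        z = np.clip(slope * (x - m), -300, 300)
        p = 10.0**z
        inv = 1.0 / (1.0 + p)
        s = p * inv * inv  # 10^z / (1+10^z)^2
        return inv, s

    if fix_front:
        def residual(theta):
            back, slope, m = theta
            return four_pl(x, 1.0, back, slope, m) - v

        def jacobian(theta):
            back, slope, m = theta
            inv, s = _parts(1.0, back, slope, m)
            amp = 1.0 - back
            return np.column_stack([
                1.0 - inv,
                -amp * _LN10 * s * (x - m),
                amp * _LN10 * s * slope,
            ])
        lower = [-1.0, -15.0, x.min() - 3.0]
        upper = [2.0, 15.0, x.max() + 3.0]
        def make_start(i):
            return [
                np.clip(v_lo + 0.05 * spread * rng.standard_normal(), -1.0, 2.0),
                1.0 + 0.3 * rng.standard_normal(),
                quantiles[i % len(quantiles)],
            ]
    else:
        def residual(theta):
            front, back, slope, m = theta
            return four_pl(x, front, back, slope, m) - v

        def jacobian(theta):
            front, back, slope, m = theta
            inv, s = _parts(front, back, slope, m)
            amp = front - back
            return np.column_stack([
                inv,
                1.0 - inv,
                -amp * _LN10 * s * (x - m),
                amp * _LN10 * s * slope,
            ])
        lower = [-1.0, -1.0, -15.0, x.min() - 3.0]
        upper = [3.0, 3.0, 15.0, x.max() + 3.0]
        def make_start(i):
            return [
                np.clip(v_hi + 0.05 * spread * rng.standard_normal(), -1.0, 3.0),
                np.clip(v_lo + 0.05 * spread * rng.standard_normal(), -1.0, 3.0),
                1.0 + 0.3 * rng.standard_normal(),
                quantiles[i % len(quantiles)],
            ]

    # exploration: capped iterations per start; polish: tight tolerances from
    # the best explored point only
    best, best_rss = None, np.inf
    for i in range(_N_STARTS):
        try:
            sol = optimize.least_squares(
                residual, make_start(i), jac=jacobian, bounds=(lower, upper),
                xtol=1e-8, ftol=1e-8, x_scale="jac", max_nfev=60,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if rss < best_rss:
            best, best_rss = sol.x, rss
        if best_rss <= 1e-20 * max(len(x), 1):  # exact fit: no better start exists
            break
    if best is None:
        return None, np.inf, False
    try:
        sol = optimize.least_squares(
            residual, best, jac=jacobian, bounds=(lower, upper),
            xtol=1e-12, ftol=1e-12, max_nfev=300,
        )
        rss = float(np.sum(sol.fun**2))
        if rss <= best_rss:
            best, best_rss = sol.x, rss
        ok = bool(sol.success) or rss <= best_rss
    except Exception:
        ok = True  # exploration result stands
    return best, best_rss, ok


def fit_dose_response(log10_dose, viability) -> FittedCurve:
    """Fit one 4PL curve jointly over all replicate points of a pair.

    With fewer than four points the front plateau is fixed at 1 (untreated
    viability) and a three-parameter fit is used.  The reported ``p_value``
    is the nested F-test of the sigmoid against the constant-mean model; a
    non-converged fit is flagged and given p = 1.
    """
    x = np.asarray(log10_dose, dtype=float)
    v = np.asarray(viability, dtype=float)
    if x.shape != v.shape or x.ndim != 1:
        raise ValueError("log10_dose and viability must be equal-length 1-D arrays")
    n = len(x)
    if len(np.unique(x)) < 2:
        raise ValueError("curve fitting needs at least 2 distinct doses")
    fix_front = n < 4
    n_par = 3 if fix_front else 4

    theta, rss1, converged = _fit_least_squares(x, v, fix_front)
    if theta is None:
        theta = [np.nan] * n_par
        rss1, converged = float("nan"), False
    if fix_front:
        front, (back, slope, m) = 1.0, theta
    else:
        front, back, slope, m = theta

    rss0 = float(np.sum((v - v.mean()) ** 2))
    if not converged or n <= n_par or not np.isfinite(rss1):
        p_value = 1.0
    elif rss0 <= 1e-14:  # perfectly flat data: the flat null is exact
        p_value = 1.0
    elif rss1 <= 0:
        p_value = 0.0
    else:
        f = ((rss0 - rss1) / (n_par - 1)) / (rss1 / (n - n_par))
        p_value = float(stats.f.sf(max(f, 0.0), n_par - 1, n - n_par))

    return FittedCurve(
        front=float(front),
        back=float(back),
        slope=float(slope),
        pec50=float(-m),
        p_value=p_value,
        ec50=float(10.0**m),
        converged=converged,
        rss=rss1,
        n_points=n,
    )


def derive_ic50(fit: FittedCurve) -> float | None:
    """Absolute IC50: the dose (µM) where fitted viability crosses 0.5.

    Defined only when front and back bracket 0.5; the closed-form inversion
    of the 4PL is used.  Returns None when the curve never crosses 0.5.
    """
    front, back, slope = fit.front, fit.back, fit.slope
    if not np.isfinite(slope) or slope == 0:
        return None
    ratio = (front - 0.5) / (0.5 - back)
    if ratio <= 0:  # 0.5 not strictly between the plateaus
        return None
    log_ic50 = -fit.pec50 + np.log10(ratio) / slope
    return float(10.0**log_ic50)


def compute_auc(fit: FittedCurve, dosed_range: tuple[float, float]) -> float:
    """Mean fitted viability over the dosed log10 range (lower = sensitive)."""
    dmin, dmax = dosed_range
    if not (0 < dmin < dmax):
        raise ValueError(f"invalid dosed range: {dosed_range}")
    grid = np.linspace(np.log10(dmin), np.log10(dmax), _AUC_GRID)
    return float(np.trapezoid(fit.viability(grid), grid) / (grid[-1] - grid[0]))


def apply_validity_filters(fit: FittedCurve, dosed_range: tuple[float, float]) -> FittedCurve:
    """Set QC flags: EC50 must lie inside the dosed range; IC50 within 10× of it.

    The EC50 flag is informational (the value is kept); an out-of-band IC50
    is removed outright, along with its natural log.
    """
    dmin, dmax = dosed_range
    if not (0 < dmin < dmax):
        raise ValueError(f"invalid dosed range: {dosed_range}")
    out = replace(fit)
    out.ec50_valid = bool(fit.converged and dmin <= fit.ec50 <= dmax)
    if out.ic50 is not None and not (dmin / 10.0 <= out.ic50 <= dmax * 10.0):
        out.ic50 = None
        out.ln_ic50 = None
    return out


def fit_viability_table(raw: pd.DataFrame, dose_range_per: str = "drug") -> pd.DataFrame:
    """Normalize, fit, and QC every drug–cell-line pair of a raw screen.

    ``dose_range_per`` chooses whether the dosed range used for AUC and
    validity comes from all observations of the drug (default, so pairs of
    one drug share a dosage group) or from the pair itself.  Returns one row
    per pair with the fitted parameters, derived measures, flags, and a
    ``dosage_group`` label — p-values are only comparable within one group.
    """
    table = normalize_viability(raw)
    if dose_range_per not in ("drug", "pair"):
        raise ValueError("dose_range_per must be 'drug' or 'pair'")
    drug_ranges = table.groupby("drug_id")["dose"].agg(["min", "max"])
    rows = []
    for (cell, drug), grp in table.groupby(["cell_line_id", "drug_id"], sort=True):
        if grp["dose"].nunique() < 2:
            raise ValueError(f"pair ({cell!r}, {drug!r}) has fewer than 2 distinct doses")
        if dose_range_per == "drug":
            dmin, dmax = float(drug_ranges.loc[drug, "min"]), float(drug_ranges.loc[drug, "max"])
        else:
            dmin, dmax = float(grp["dose"].min()), float(grp["dose"].max())
        fit = fit_dose_response(np.log10(grp["dose"].to_numpy()), grp["viability"].to_numpy())
        fit.ic50 = derive_ic50(fit)
        fit.auc = compute_auc(fit, (dmin, dmax)) if fit.converged else None
        if fit.ic50 is not None:
            fit.ln_ic50 = float(np.log(fit.ic50))
        fit = apply_validity_filters(fit, (dmin, dmax))
        doses = tuple(sorted(grp["dose"].unique()))
        rows.append(
            {
                "cell_line_id": cell,
                "drug_id": drug,
                "front": fit.front,
                "back": fit.back,
                "slope": fit.slope,
                "pEC50": fit.pec50,
                "EC50": fit.ec50,
                "IC50": fit.ic50,
                "LN_IC50": fit.ln_ic50,
                "AUC": fit.auc,
                "p_value": fit.p_value,
                "ec50_valid": fit.ec50_valid,
                "dosage_group": f"{drug}:{hash(doses) & 0xFFFFFFFF:08x}",
            }
        )
    return pd.DataFrame(rows)
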