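"""Evaluation metrics: plain, bias-normalized, stratified, and SSMD effect sizes.

The central trap in drug response evaluation is that global metrics over a
cell-line × drug table are inflated by between-drug (and between-cell-line)
mean differences — Simpson's paradox at benchmark scale.  Two remedies are
provided here: normalized metrics, computed after subtracting a mean-effects
baseline's predictions from both truth and prediction, and stratified
metrics, computed per drug or per cell line over predictions pooled across
folds.

Correlations with a zero-variance argument are undefined and reported as NaN,
never coerced to 0; aggregation steps must exclude them explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

#: Minimum points for a stratified metric to be defined.
MIN_STRATUM_SIZE = 3

#: Sentinel for an SSMD with a non-zero mean difference but zero spread.
SSMD_INF = float("inf")


@dataclass(frozen=True)
class MetricSuite:
    """One set of regression metrics; NaN marks undefined correlations."""

    mse: float
    rmse: float
    mae: float
    r2: float
    pearson: float
    spearman: float
    kendall: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _safe_corr(func, a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = func(a, b)[0]
    return float(r)


def compute_metric_suite(y_true, y_pred) -> MetricSuite:
    """MSE, RMSE, MAE, R², and Pearson/Spearman/Kendall correlations.

    R² is 1 − Σ(y−ŷ)²/Σ(y−ȳ)²; rank correlations use average ranks for
    ties.  With fewer than two points the error metrics are still defined but
    every correlation (and R²) is NaN.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if not (np.isfinite(y_true).all() and np.isfinite(y_pred).all()):
        raise ValueError("metric inputs must be finite")
    n = len(y_true)
    if n == 0:
        raise ValueError("cannot compute metrics on empty input")
    err = y_true - y_pred
    mse = float(np.mean(err**2))
    suite = {
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "mae": float(np.mean(np.abs(err))),
        "n": n,
    }
    if n < 2:
        suite.update(r2=float("nan"), pearson=float("nan"), spearman=float("nan"), kendall=float("nan"))
        return MetricSuite(**suite)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    suite["r2"] = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    suite["pearson"] = _safe_corr(stats.pearsonr, y_true, y_pred)
    suite["spearman"] = _safe_corr(stats.spearmanr, y_true, y_pred)
    suite["kendall"] = _safe_corr(stats.kendalltau, y_true, y_pred)
    return MetricSuite(**suite)


def normalized_metric_suite(y_true, y_pred, naive_pred) -> MetricSuite:
    """Metrics on mean-effect residuals: (y−naive) vs (ŷ−naive).

    ``naive_pred`` must come from a mean-effects baseline fitted on the same
    training fold as the model that produced ``y_pred``.  The result isolates
    differential drug response — whatever signal remains once additive drug
    and cell-line effects are removed.  Negative normalized R² values are
    stored as-is; clipping at zero is a rendering decision, not a metric one.
    """
    naive_pred = np.asarray(naive_pred, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if not (len(y_true) == len(y_pred) == len(naive_pred)):
        raise ValueError("y_true, y_pred and naive_pred must have equal lengths")
    return compute_metric_suite(y_true - naive_pred, y_pred - naive_pred)


def per_fold_metric_table(predictions: pd.DataFrame) -> pd.DataFrame:
    """Plain and normalized metric suites per (model, fold).

    ``predictions`` is the harness output table.  Returns long-format rows
    (model, fold, metric, value, normalized).
    """
    rows = []
    for (model, fold), grp in predictions.groupby(["model", "fold"], sort=True):
        plain = compute_metric_suite(grp["y_true"], grp["y_pred"])
        norm = normalized_metric_suite(grp["y_true"], grp["y_pred"], grp["y_naive"])
        for normalized, suite in ((False, plain), (True, norm)):
            for metric, value in suite.as_dict().items():
                if metric == "n":
                    continue
                rows.append(
                    {"model": model, "fold": fold, "metric": metric,
                     "value": value, "normalized": normalized, "n": suite.n}
                )
    return pd.DataFrame(rows)


def stratified_metrics(predictions: pd.DataFrame, by: str = "drug") -> pd.DataFrame:
    """Per-drug or per-cell-line metrics over predictions pooled across folds.

    Strata with fewer than :data:`MIN_STRATUM_SIZE` points get NaN metrics
    but keep their size in the output, so small-stratum attrition is visible.
    """
    if by not in ("drug", "cell_line"):
        raise ValueError(f"stratify by 'drug' or 'cell_line', got {by!r}")
    key = "drug_id" if by == "drug" else "cell_line_id"
    rows = []
    for (model, stratum), grp in predictions.groupby(["model", key], sort=True):
        if len(grp) >= MIN_STRATUM_SIZE:
            suite = compute_metric_suite(grp["y_true"], grp["y_pred"]).as_dict()
        else:
            suite = {m: float("nan") for m in ("mse", "rmse", "mae", "r2", "pearson", "spearman", "kendall")}
            suite["n"] = len(grp)
        rows.append({"model": model, "stratum_kind": by, "stratum": stratum, **suite})
    return pd.DataFrame(rows)


def ssmd_effect_size(values_a, values_b, paired: bool = True) -> float:
    """Strictly standardized mean difference between two per-fold metric series.

    The paired form (default; folds are natural pairs) is
    mean(a−b) / sd(a−b) with the sample standard deviation.  Conventions for
    degenerate spreads: identical series give 0; a constant non-zero
    difference gives a signed infinity.  ``paired=False`` uses the unpaired
    form (mean(a)−mean(b)) / sqrt(var(a)+var(b)).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) and paired:
        raise ValueError("paired SSMD requires equal-length, fold-paired inputs")
    if min(len(a), len(b)) < 2:
        raise ValueError("SSMD needs at least two values per group")
    if paired:
        d = a - b
        num = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
    else:
        num = float(np.mean(a) - np.mean(b))
        sd = float(np.sqrt(np.var(a, ddof=1) + np.var(b, ddof=1)))
    if sd <= 1e-12 * max(1.0, abs(num)):
        return 0.0 if abs(num) <= 1e-12 else float(np.sign(num)) * SSMD_INF
    return num / sd
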