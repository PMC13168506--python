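"""Rank-based model comparison: Friedman omnibus, Conover post-hoc, CD groups.

Models are ranked within each cross-validation fold by MSE (rank 1 = lowest
error, average ranks for ties).  The Friedman test asks whether the rank
profiles could be exchangeable across models; the Conover–Iman post-hoc then
localizes which pairs differ, with Benjamini–Hochberg control over the
pairwise family.  Critical-difference grouping turns the adjusted p matrix
into the horizontal bars of a CD diagram: each bar is a maximal contiguous
run of mean-rank-ordered models with no significant internal pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class RankMatrix:
    """Fold × model rank matrix; each row ranks models by MSE within a fold."""

    ranks: np.ndarray  # shape (n folds, k models)
    models: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.ranks.shape[0]

    @property
    def k(self) -> int:
        return self.ranks.shape[1]

    @property
    def mean_ranks(self) -> pd.Series:
        return pd.Series(self.ranks.mean(axis=0), index=list(self.models))


def rank_matrix_from_metrics(metric_table: pd.DataFrame, metric: str = "mse",
                             normalized: bool = False) -> RankMatrix:
    """Build the fold × model rank matrix from a per-fold metric table."""
    sub = metric_table[(metric_table["metric"] == metric) & (metric_table["normalized"] == normalized)]
    wide = sub.pivot(index="fold", columns="model", values="value").sort_index()
    if wide.isna().any().any():
        raise ValueError("every model needs a metric value in every fold to be ranked")
    ranks = np.vstack([stats.rankdata(row) for row in wide.to_numpy()])
    return RankMatrix(ranks=ranks, models=tuple(wide.columns))


def friedman_test(ranks: RankMatrix | np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman test on a fold × model rank matrix.

    With A = Σ r_ij² and C = nk(k+1)²/4, the statistic is
    Q = (k−1) · Σ_j (R_j − n(k+1)/2)² / (A − C),
    which reduces to the textbook 12/(nk(k+1))·ΣR_j² − 3n(k+1) when there
    are no ties.  The p-value is the upper χ² tail with k−1 degrees of
    freedom.  Complete ties in every fold give Q = 0, p = 1.
    """
    r = ranks.ranks if isinstance(ranks, RankMatrix) else np.asarray(ranks, dtype=float)
    n, k = r.shape
    if n < 2 or k < 2:
        raise ValueError(f"Friedman test needs >=2 folds and >=2 models, got n={n}, k={k}")
    col_sums = r.sum(axis=0)
    a1 = float(np.sum(r**2))
    c1 = n * k * (k + 1) ** 2 / 4.0
    denom = a1 - c1
    if denom <= 0:  # all models tied in every fold
        return 0.0, 1.0
    q = (k - 1) * float(np.sum((col_sums - n * (k + 1) / 2.0) ** 2)) / denom
    return q, float(stats.chi2.sf(q, df=k - 1))


def conover_posthoc(ranks: RankMatrix) -> pd.DataFrame:
    """Pairwise Conover–Iman test on Friedman rank sums, BH-adjusted.

    The statistic for models i, j is the two-sample t of a rank-based
    two-way layout:  t = (R_i − R_j) / sqrt(2n·SSE/((n−1)(k−1))), where
    SSE = Σ r² − (1/n)Σ_j R_j² is the residual sum of squares of the ranks
    after removing fold and model effects, and the reference distribution is
    Student t with (n−1)(k−1) degrees of freedom.  Returns a long table with
    columns (model_a, model_b, p_raw, p_adjusted) over the upper triangle;
    use :func:`posthoc_matrix` for the symmetric matrix form.
    """
    r = ranks.ranks
    n, k = ranks.n, ranks.k
    if n < 2 or k < 2:
        raise ValueError("Conover post-hoc needs >=2 folds and >=2 models")
    col_sums = r.sum(axis=0)
    a1 = float(np.sum(r**2))
    b1 = float(np.sum(col_sums**2)) / n
    sse = a1 - b1
    df = (n - 1) * (k - 1)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if sse <= 1e-12:
        # Zero residual rank variance: identical rank sums (e.g. all models
        # tied in every fold) are indistinguishable (p=1); different rank
        # sums with zero noise are infinitely separated (p=0).
        p_raw = np.array(
            [1.0 if col_sums[i] == col_sums[j] else 0.0 for i, j in pairs]
        )
    else:
        se = np.sqrt(2.0 * n * sse / df)
        p_raw = np.array(
            [2.0 * stats.t.sf(abs(col_sums[i] - col_sums[j]) / se, df=df) for i, j in pairs]
        )
    p_adj = multipletests(p_raw, method="fdr_bh")[1] if len(pairs) else np.array([])
    return pd.DataFrame(
        {
            "model_a": [ranks.models[i] for i, _ in pairs],
            "model_b": [ranks.models[j] for _, j in pairs],
            "p_raw": p_raw,
            "p_adjusted": np.minimum(p_adj, 1.0),
        }
    )


def posthoc_matrix(posthoc: pd.DataFrame, models: tuple[str, ...],
                   column: str = "p_adjusted") -> pd.DataFrame:
    """Symmetric p-value matrix (diagonal 1) from the long post-hoc table."""
    mat = pd.DataFrame(np.ones((len(models), len(models))), index=list(models), columns=list(models))
    for _, row in posthoc.iterrows():
        mat.loc[row["model_a"], row["model_b"]] = row[column]
        mat.loc[row["model_b"], row["model_a"]] = row[column]
    return mat


def cd_groups(mean_ranks: pd.Series, adjusted_p: pd.DataFrame,
              alpha: float = DEFAULT_ALPHA) -> list[tuple[str, ...]]:
    """Critical-difference bars over models ordered by mean rank.

    For each model, grow the maximal contiguous run (in mean-rank order)
    containing it in which every pair has adjusted p ≥ alpha; nested and
    duplicate runs are merged.  All pairwise significance ⇒ singleton bars;
    no significant pair ⇒ one bar spanning all models.
    """
    order = list(mean_ranks.sort_values(kind="stable").index)
    m = len(order)

    def compatible(i: int, j: int) -> bool:
        return all(
            adjusted_p.loc[order[a], order[b]] >= alpha
            for a in range(i, j + 1)
            for b in range(a + 1, j + 1)
        )

    bars: list[tuple[int, int]] = []
    for i in range(m):
        lo = hi = i
        while hi + 1 < m and compatible(lo, hi + 1):
            hi += 1
        while lo - 1 >= 0 and compatible(lo - 1, hi):
            lo -= 1
        bars.append((lo, hi))
    # drop bars nested inside another bar, keep unique maximal spans
    maximal = [
        (lo, hi)
        for lo, hi in set(bars)
        if not any((l2 <= lo and hi <= h2) and (l2, h2) != (lo, hi) for l2, h2 in set(bars))
    ]
    return [tuple(order[lo : hi + 1]) for lo, hi in sorted(maximal)]


def compare_models(metric_table: pd.DataFrame, metric: str = "mse",
                   alpha: float = DEFAULT_ALPHA) -> dict:
    """One-call rank comparison: Friedman, Conover+BH, and CD grouping.

    The post-hoc is always computed; when the omnibus p is above ``alpha``
    the result carries ``omnibus_significant=False`` so reports can flag
    that pairwise findings lack omnibus support.
    """
    ranks = rank_matrix_from_metrics(metric_table, metric=metric)
    q, p = friedman_test(ranks)
    posthoc = conover_posthoc(ranks)
    pmat = posthoc_matrix(posthoc, ranks.models)
    groups = cd_groups(ranks.mean_ranks, pmat, alpha=alpha)
    return {
        "friedman_q": q,
        "friedman_p": p,
        "omnibus_significant": p < alpha,
        "mean_ranks": ranks.mean_ranks,
        "posthoc": posthoc,
        "cd_groups": groups,
        "alpha": alpha,
    }
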