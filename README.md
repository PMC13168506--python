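# drbench

Bias-aware benchmarking of drug response prediction models.

## The problem

Models that predict the sensitivity of cancer cell lines to drugs (ln IC50,
EC50, pEC50, AUC) are usually evaluated on large screens of cell-line × drug
pairs.  Those tables are dominated by *additive* structure: most of the
variance in ln IC50 comes from which drug was applied, a smaller share from
which cell line, and only a minority from the cell-by-drug interaction that
models are actually supposed to learn.  Three consequences routinely inflate
reported performance:

* **Simpson's paradox** — a high global correlation can coexist with
  near-zero within-drug correlations, because the global metric is driven by
  between-drug mean differences.
* **Pseudoreplication** — hundreds of thousands of pairs built from a few
  hundred cell lines and drugs are not independent samples.
* **Leakage** — random splits let models memorize the entities they will be
  tested on.

`drbench` is an evaluation harness that makes these failure modes visible
and controllable.  It is aimed at method developers and reviewers who need
to know whether a model learns differential drug response or merely the
marginal means.

## What it provides

* **Naive baselines** as scikit-learn estimators.  The central one is the
  mean-effects predictor

  ŷᵢⱼ = μᵢᶜ + μⱼᵈ − μ

  (cell-line mean + drug mean − overall training mean, falling back to μ for
  unseen entities).  On completely crossed additive data this equation is
  exact; any model that cannot beat it has learned nothing beyond dataset
  biases.
* **Application-specific cross-validation**: leave-pair-out (LPO),
  leave-cell-line-out (LCO), leave-tissue-out (LTO), leave-drug-out (LDO),
  with runtime leakage guards, group-disjoint inner validation splits, and
  grid-search tuning on validation RMSE.
* **Bias-aware metrics**: MSE/RMSE/MAE/R²/Pearson/Spearman/Kendall per fold,
  *normalized* variants computed on residuals after subtracting the
  mean-effects baseline, per-drug / per-cell-line stratified metrics, and
  SSMD effect sizes.
* **Rank statistics**: tie-corrected Friedman test on per-fold MSE ranks,
  Conover–Iman post-hoc with Benjamini–Hochberg correction, and
  critical-difference grouping.
* **Ablation randomizers**: feature permutation across entities,
  moment-preserving Gaussian randomization, degree-preserving edge shuffles
  for graph features, with paired per-fold ΔR² and ±1.96·SEM bands.
* **Cross-study evaluation** with split-mode-specific overlap exclusion.
* **Dose-response preprocessing**: per-replicate control normalization,
  joint 4PL fitting across replicates, an F-test against the flat model,
  IC50/EC50/pEC50/AUC derivation, and range-based validity filters.
* **A synthetic-data generator** whose dials are the variance shares of the
  additive decomposition, so every claim above is testable without any
  download.

## Worked example

```python
from drbench.reporting import run_from_config

out = run_from_config({
    "synthetic": {"n_cell_lines": 60, "n_drugs": 30, "completeness": 0.8},
    "models": ["naive_overall", "naive_drug_mean", "naive_mean_effects"],
    "mode": "LCO", "k": 5, "seed": 7,
}, "demo_run")
print((out / "summary.txt").read_text())
```

prints

```
Mean per-fold metrics (R2 clipped at 0 for display):
metric                     mse        pearson            r2
normalized               False  True    False  True   False True
mode model
LCO  naive_drug_mean     0.354  0.354   0.813  0.006  0.644   0.0
     naive_mean_effects  0.354  0.354   0.813    NaN  0.644   0.0
     naive_overall       1.009  1.009     NaN  0.018  0.000   0.0

LCO: Friedman Q=10.000, p=0.006738

Critical-difference groups (models not significantly different):
  LCO bar 0: naive_drug_mean (1.50), naive_mean_effects (1.50)
  LCO bar 1: naive_overall (3.00)
```

Reading this: under LCO the test cell lines are unseen, so the mean-effects
predictor degenerates to the drug-mean predictor — identical rows.  Their
plain R² of 0.64 looks impressive but is pure drug-mean memorization: the
*normalized* R² (after subtracting the mean-effects baseline) is zero, and
the normalized Pearson is near zero or undefined.  The Friedman/Conover
block confirms the two drug-aware baselines are indistinguishable from each
other and better-ranked than the overall mean.

The same run is available from the shell:

```bash
drbench run --config config.yaml --out demo_run
drbench curves --viability raw.csv --out curves.csv
drbench simulate --seed 1 --out synthetic/
```

All results are written as CSVs (`predictions.csv`, `metrics_per_fold.csv`,
`metrics_stratified.csv`, `friedman_conover.csv`, `cd_groups.csv`,
`ablation.csv`) with unclipped values; clipping of negative normalized R²
happens only in the rendered summary.

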