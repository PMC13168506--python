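# Methods

This note documents the statistical machinery in `drbench`: the models and
conventions, the dials of the synthetic generator, numerical choices, and
what the test suite does and does not establish about real data.

## Response data model

A response dataset is a long-format table keyed by (cell line, drug) with
exactly one measure (ln IC50 by default; IC50, EC50, pEC50, AUC, or a custom
name).  Multiple rows per pair are replicates and stay distinguishable by
row position; every grouping operation (splits, naive means) treats the pair
as the unit where the design requires it.  Identifiers are opaque strings —
no accession mapping is attempted.  Files are comma-separated UTF-8 with a
decimal point; a round trip through CSV preserves records, measure, and
order exactly.  Missing tissue is tolerated everywhere except the LTO split,
which checks at split time.

## Naive predictor family

Five feature-free baselines, all fitted on training records only:

| variant | prediction | fallback |
|---|---|---|
| overall | μ (training mean) | — |
| drug_mean | μⱼᵈ | μ for unseen drugs |
| cell_line_mean | μᵢᶜ | μ for unseen cell lines |
| tissue_mean | mean over training cell lines of the tissue | μ for unseen tissues |
| mean_effects | μᵢᶜ + μⱼᵈ − μ | per-entity fallback to μ |

The mean-effects equation is exact on completely crossed additive data;
this identity (and agreement with a brute-force two-way-means oracle to
1e−12) is asserted in the tests.  The tissue fallback to μ is our choice —
the fallback rule is only specified for drugs and cell lines, and the
symmetric choice keeps predictions defined everywhere.

## Splits

Grouping keys are pairs (LPO), cell lines (LCO), tissues (LTO), or drugs
(LDO).  Keys are shuffled with the run seed and dealt round-robin to k
folds, balancing *group counts* (record-count balancing is deliberately not
promised).  The inner split is a single group-disjoint holdout (default 10%
of training groups; a further 10% for early stopping when a model requests
it), not an inner cross-validation.  Tuning evaluates the full grid in
order on validation RMSE; ties keep the earlier configuration; the winner
is refit on the full outer-training set only, so the validation set is
treated identically for early-stopping and ordinary models.  LTO with more
folds than tissues is an error rather than a silent merge.  A runtime guard
re-checks group disjointness between every test fold and everything the
fitted model saw.

## Metrics

R² is 1 − Σ(y−ŷ)²/Σ(y−ȳ)².  Correlations with a zero-variance argument are
undefined and propagate as NaN — never coerced to zero — and are excluded
from averages by the caller, visibly.  Normalized metrics recompute the
suite on (y − naive) vs (ŷ − naive), where the naive predictions come from
a mean-effects model fitted on the *same training fold* as the evaluated
model (the leakage-consistent choice; fitting it once on all data would let
test information into the reference).  Stored values are never clipped;
rendering negative normalized R² as zero is done only in the text summary.
Stratified metrics pool predictions across folds and require at least 3
points per stratum (per-drug fits in sparse screens can be that small);
smaller strata are reported as undefined together with their size.

SSMD uses the paired form mean(a−b)/sd(a−b) by default because folds pair
naturally; the unpaired form is available behind a switch.  Conventions for
degenerate spreads: identical series → 0, constant non-zero difference →
signed infinity.

A caution that the tests quantify: when a predictor is itself a training
group mean (e.g. the drug-mean baseline under LPO), pooling predictions
across folds induces a leave-fold-out anticorrelation within each group of
roughly −1/√(points per group per fold).  Per-group correlations of such
baselines are therefore slightly negative, not zero, unless strata are
large; interpretation of stratified metrics should keep this in mind.

## Rank statistics

Models are ranked per fold by MSE with average ranks for ties.  The
Friedman statistic uses the tie-corrected form
Q = (k−1)·Σⱼ(Rⱼ − n(k+1)/2)² / (A − C) with A = Σ rᵢⱼ² and
C = nk(k+1)²/4, with the upper χ²(k−1) tail.  The post-hoc is the
Conover–Iman statistic t = (Rᵢ − Rⱼ)/√(2n·SSE/((n−1)(k−1))) with
SSE = A − (1/n)ΣRⱼ², referred to Student t with (n−1)(k−1) degrees of
freedom — algebraically the pairwise contrast of a two-way ANOVA on the
ranks, which is exactly how the test suite cross-checks it (statsmodels OLS
contrast).  Benjamini–Hochberg is applied over the k(k−1)/2 upper-triangle
p-values.  Zero residual rank variance is split into two cases: equal rank
sums → p = 1, different rank sums → p = 0.  The omnibus and the post-hoc
are always both computed; when the omnibus p ≥ α (default 0.05) the result
carries an explicit flag instead of suppressing the pairwise table.
Critical-difference bars are maximal contiguous runs in mean-rank order
with no significant internal pair, with nested bars merged.

## Ablation and robustness

Three randomizers, each destroying a different level of structure:
permutation of the entity→vector assignment (multiset of vectors
preserved), per-column moment-preserving Gaussian replacement (means and
sample sds preserved; the per-entity variant is available behind a switch),
and degree-preserving double-edge swaps for graphs (default 10× edge count
attempted swaps; graphs with no legal swap return unchanged).  Ablations
retrain the model from scratch on randomized features with the same tuned
hyperparameters — re-tuning is deliberately skipped to isolate the feature
signal, and merely re-predicting with the old fit is not supported because
it understates what a model could still extract.  Deltas are paired per
fold, with a ±1.96·SEM band.  Robustness refits repeat the fit across
initialization seeds and report the metric spread; zero spread for a
deterministic model is a result, not an error.

## Cross-study evaluation

External records that the training fold has already seen are excluded
before scoring: overlapping pairs (LPO), cell lines (LCO), tissues (LTO),
or drugs (LDO).  Exclusion is against the individual training fold's
entities by default — each fold model is an independent experiment — with a
union-over-folds mode available.  The naive mean-effects reference is
fitted on the same training fold and scored on the identical filtered
records, so normalized external metrics remain comparable to within-study
ones.  Records lacking required features are dropped with counts, not
imputed.

## Dose-response curves

Signals are normalized per replicate by that replicate's no-drug control;
values above 1 (growth stimulation) are retained.  One four-parameter
log-logistic curve

v(x) = back + (front − back)/(1 + 10^(slope·(x − log10 EC50)))

is fitted jointly to all replicate points of a pair in log10-dose space
(doses in µM; positive slope = viability decreasing with dose).  pEC50 is
−log10(EC50 [µM]); an offset of +6 converts to the molar convention.
With fewer than four points the front plateau is fixed at 1.  The
significance measure is a plain nested F-test of the sigmoid against the
constant-mean model — under flat-truth simulation its small-p rate is at or
below nominal (the test suite checks ≤7% below 0.05 over 1000 noisy flat
curves).  Because dosage ranges differ between drugs, fits carry a dosage
group label and p-values should only be compared within one group.

IC50 is the absolute half-viability crossing, solved in closed form when
front and back bracket 0.5 and missing otherwise.  AUC is the mean *fitted*
viability over the dosed log10 range (so it lives in the same units as
viability and lower means more sensitive); integrating the fitted rather
than the raw curve is a documented choice, not a universal convention.
Validity rules: EC50 outside [dmin, dmax] is flagged invalid; IC50 outside
[dmin/10, dmax·10] (one order of magnitude beyond the dosed range, boundary
inclusive) is removed.

Numerics: bounded trust-region least squares with an analytic Jacobian,
five starts (EC50 at dose quantiles, plateaus at viability extremes, small
fixed-seed jitter) run with capped iterations, then a tight polish from the
best start.  Noiseless curves are recovered to pEC50 error below 1e−3
(tested at 1e−9 in practice); non-convergence flags the curve and forces
p = 1.

## Synthetic generator

y(i,j) = μ0 + cᵢ + dⱼ + t(i) + uᵢᵀWvⱼ + ε, with tissue assigned to cell
lines round-robin.  Effect vectors are drawn Gaussian and then standardized
to zero mean and *exactly* the configured sd: realized variance shares are
then the dials, whereas raw draws would fluctuate by ±sd²·√(2/n) — far too
loose at realistic entity counts for any share-based assertion.  The
interaction matrix is likewise rescaled empirically after setting
‖W‖_F = sd_interaction (the population identity Var(uᵀWv) = ‖W‖_F²).
Noise is left raw; at typical record counts its share converges on its own.

Default shares mirror the decomposition observed in large pan-cancer
screens: drug 0.675, cell line 0.035, tissue 0.025 (so a cell-line-mean
predictor, which absorbs tissue, captures 0.060, and the mean-effects
baseline 0.735), with the unexplained remainder split as interaction 0.10
and noise 0.165.  Completeness defaults to 0.8, the order of the densest
public screens.  Pair sampling is uniform without replacement; in very
sparse regimes coverage of every entity is enforced by seeding one record
per cell line and drug (with a warning).  All randomness derives from one
root seed through named `SeedSequence` streams, so each artifact
(effects, latents, sampling, noise, features, graphs) is independently
reproducible.

Feature sets expose the generating quantities: the first informative column
is the entity's additive effect, the next ones its latent interaction
factors, further informative columns random mixtures of those, the rest iid
noise; `informative_fraction` sets the split.  The drug graph modality
encodes effect-size terciles as the edge density of small random graphs.
The generator emulates the *variance structure* of real screens, not their
marginals: omics features are not log-normal, drugs have no chemical-space
geometry, and tissue assignment is balanced by construction.  Passing tests
therefore demonstrate correctness of the evaluation machinery under the
assumed decomposition, not predictive performance on any real screen.

Raw viability screens are generated from known 4PL parameters (front 1,
back ~ U(0, 0.2), Hill slope ~ U(0.7, 2), EC50 log-uniform in the dosed
range) with Gaussian noise on the viability scale, signals scaled by a
constant control.

## Problem sizes used in the checks

The quantitative assertions run at sizes where their statements are sharp:
the bias floor of the overall-mean predictor at 400×250 complete pairs
(the rounding statement is asymptotic; at a few thousand test points per
fold the finite-sample bias of order −1/n_test would still round away from
zero), variance-share recovery at 300×150, the Simpson construction at
2000×50 (per-drug strata need ~200 points per fold so the leave-fold-out
anticorrelation described above stays within ±0.1), rank-test calibration
over 2000 simulated benchmarks of 10 folds × 5 models, and curve recovery
over 100 curves of 8 doses × 2 replicates.

## Known limitations

* Reference learners (ridge, bilinear ridge, random forest, per-drug ridge)
  exercise the harness; they are not re-implementations of published
  networks, and the bilinear model is intentionally matched to the
  generator's interaction form.
* The curve-fit p-value is a plain F-test; no recalibration against an
  empirical null is attempted, so p-values are comparable within a dosage
  group but are not calibrated error rates across heterogeneous designs.
* The AUC normalization and the train-only refit after tuning are fixed,
  documented choices among defensible alternatives.
* No batch-effect correction or feature harmonization is performed for
  cross-study evaluation; distribution shift shows up in the metrics, as
  intended.
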