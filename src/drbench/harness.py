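"""Benchmark execution: grid-search tuning and cross-validated prediction.

The harness owns everything that can leak: it builds the outer folds, carves
the inner holdout (and early-stopping) validation sets group-disjointly, runs
the grid search on validation RMSE, refits the winner on the full outer
training set, and asserts at run time that no test grouping key was visible
during fitting.  Alongside every model it fits the mean-effects baseline on
the identical training records, so normalized metrics can be computed
downstream from the same prediction table.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from drbench.data import FeatureSet, ResponseDataset
from drbench.models import ModelSpec, NaiveResponseModel
from drbench.splits import FoldAssignment, SplitMode, _group_keys, make_folds, make_inner_split

logger = logging.getLogger("drbench")


@dataclass
class TunedModel:
    """Winner of one fold's grid search, refit on that fold's training set."""

    spec: ModelSpec
    params: dict
    estimator: object
    fold: int
    validation_rmse: float
    train_cell_lines: frozenset
    train_drugs: frozenset
    train_tissues: frozenset
    train_pairs: frozenset


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(y_true) - np.asarray(y_pred)) ** 2)))


def grid_search_tune(
    spec: ModelSpec,
    train_df: pd.DataFrame,
    y: np.ndarray,
    mode: SplitMode | str,
    seed: int,
    features: dict[str, FeatureSet] | None = None,
    val_fraction: float = 0.1,
    fold: int = -1,
) -> TunedModel:
    """Tune one model on an outer-training table and refit the winner.

    Every configuration of the grid (Cartesian product, grid order) is
    trained on the inner-train part and scored by RMSE on the group-disjoint
    inner-validation part; ties keep the earlier configuration.  Models with
    an empty grid skip the inner loop entirely.  The chosen configuration is
    refit on the full outer-training set; the inner validation set is not
    folded back in, so early-stopping and non-early-stopping models see the
    same amount of data.
    """
    mode = SplitMode(mode)
    train_df = train_df.reset_index(drop=True)
    y = np.asarray(y, dtype=float)

    if spec.grid:
        names = list(spec.grid.keys())
        combos = [dict(zip(names, vals)) for vals in itertools.product(*spec.grid.values())]
    else:
        combos = [{}]
    if not combos:
        raise ValueError(f"model {spec.name} has an empty hyperparameter grid")

    best_params, best_rmse = combos[0], np.inf
    if len(combos) > 1:
        parts = make_inner_split(
            train_df, mode, val_fraction=val_fraction, seed=seed,
            early_stopping=spec.needs_early_stopping,
        )
        inner_idx, val_idx = parts[0], parts[1]
        X_inner, y_inner = train_df.iloc[inner_idx].reset_index(drop=True), y[inner_idx]
        X_val, y_val = train_df.iloc[val_idx].reset_index(drop=True), y[val_idx]
        for params in combos:
            est = spec.build(params, features=features)
            est.fit(X_inner, y_inner)
            rmse = _rmse(y_val, est.predict(X_val))
            if rmse < best_rmse:  # strict: ties keep grid order
                best_params, best_rmse = params, rmse

    final = spec.build(best_params, features=features)
    final.fit(train_df, y)
    return TunedModel(
        spec=spec,
        params=best_params,
        estimator=final,
        fold=fold,
        validation_rmse=best_rmse if np.isfinite(best_rmse) else float("nan"),
        train_cell_lines=frozenset(train_df["cell_line_id"]),
        train_drugs=frozenset(train_df["drug_id"]),
        train_tissues=frozenset(train_df["tissue"].dropna().astype(str)),
        train_pairs=frozenset(zip(train_df["cell_line_id"], train_df["drug_id"])),
    )


def _assert_no_leakage(tuned: TunedModel, test_df: pd.DataFrame, mode: SplitMode) -> None:
    """Runtime guard: test grouping keys must be invisible to the fit."""
    if mode == SplitMode.LPO:
        overlap = tuned.train_pairs & set(zip(test_df["cell_line_id"], test_df["drug_id"]))
    elif mode == SplitMode.LCO:
        overlap = tuned.train_cell_lines & set(test_df["cell_line_id"])
    elif mode == SplitMode.LTO:
        overlap = tuned.train_tissues & set(test_df["tissue"].astype(str))
    else:
        overlap = tuned.train_drugs & set(test_df["drug_id"])
    if overlap:
        raise RuntimeError(
            f"leakage: {mode.value} test fold shares grouping keys with training: "
            f"{sorted(overlap)[:5]}"
        )


def _drop_missing_features(
    df: pd.DataFrame, spec: ModelSpec, features: dict[str, FeatureSet] | None
) -> np.ndarray:
    """Boolean mask of records whose entities have all required features."""
    mask = np.ones(len(df), dtype=bool)
    for modality in spec.required_modalities:
        fs = (features or {}).get(modality)
        if fs is None:
            raise ValueError(f"model {spec.name} requires modality {modality!r}")
        id_col = "cell_line_id" if fs.entity_kind == "cell_line" else "drug_id"
        mask &= df[id_col].isin(fs.views.keys()).to_numpy()
    return mask


def run_cross_validation(
    dataset: ResponseDataset,
    models: list[ModelSpec],
    mode: SplitMode | str,
    k: int = 10,
    seed: int = 0,
    features: dict[str, FeatureSet] | None = None,
    val_fraction: float = 0.1,
    folds: FoldAssignment | None = None,
    keep_tuned: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Run the full benchmark loop and return the long prediction table.

    Output columns: ``model, fold, cell_line_id, drug_id, tissue, y_true,
    y_pred, y_naive`` — one row per test record per model, where ``y_naive``
    is the prediction of a mean-effects baseline fitted on the same training
    fold (the reference for normalized metrics).
    """
    mode = SplitMode(mode)
    folds = folds or make_folds(dataset, mode, k=k, seed=seed)
    df = dataset.df

    runnable: list[ModelSpec] = []
    for spec in models:
        if mode == SplitMode.LDO and not spec.predicts_unseen_drugs:
            warnings.warn(
                f"model {spec.name} cannot predict unseen drugs; skipped under LDO", stacklevel=2
            )
            logger.warning("model %s skipped under LDO (predicts_unseen_drugs=False)", spec.name)
            continue
        runnable.append(spec)

    rows: list[pd.DataFrame] = []
    tuned_models: dict[tuple[str, int], TunedModel] = {}
    for fold in range(folds.k):
        tr_idx, te_idx = folds.train_indices(fold), folds.test_indices(fold)
        train_df = df.iloc[tr_idx].reset_index(drop=True)
        test_df = df.iloc[te_idx].reset_index(drop=True)
        y_train = dataset.values[tr_idx]
        y_test = dataset.values[te_idx]

        naive = NaiveResponseModel(variant="mean_effects").fit(train_df, y_train)
        y_naive = naive.predict(test_df)

        for spec in runnable:
            tr_mask = _drop_missing_features(train_df, spec, features)
            te_mask = _drop_missing_features(test_df, spec, features)
            n_drop = int((~tr_mask).sum() + (~te_mask).sum())
            if n_drop:
                logger.info(
                    "model %s fold %d: dropped %d records lacking required features",
                    spec.name, fold, n_drop,
                )
            tuned = grid_search_tune(
                spec,
                train_df.loc[tr_mask],
                y_train[tr_mask],
                mode,
                seed=seed + fold,
                features=features,
                val_fraction=val_fraction,
                fold=fold,
            )
            sub_test = test_df.loc[te_mask].reset_index(drop=True)
            _assert_no_leakage(tuned, sub_test, mode)
            y_pred = tuned.estimator.predict(sub_test)
            rows.append(
                pd.DataFrame(
                    {
                        "model": spec.name,
                        "fold": fold,
                        "cell_line_id": sub_test["cell_line_id"],
                        "drug_id": sub_test["drug_id"],
                        "tissue": sub_test["tissue"],
                        "y_true": y_test[te_mask],
                        "y_pred": np.asarray(y_pred, dtype=float),
                        "y_naive": y_naive[te_mask],
                    }
                )
            )
            if keep_tuned:
                tuned_models[(spec.name, fold)] = tuned

    predictions = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["model", "fold", "cell_line_id", "drug_id", "tissue", "y_true", "y_pred", "y_naive"]
    )
    if keep_tuned:
        return predictions, tuned_models
    return predictions
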