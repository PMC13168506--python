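"""Cross-study evaluation with setting-specific overlap exclusion.

A model tuned on one screen is applied to an external screen measured with
the same response measure.  To keep the external evaluation honest under a
given split design, records that the training fold has already seen are
removed first: overlapping (cell line, drug) pairs under LPO, overlapping
cell lines under LCO, tissues under LTO, drugs under LDO.  Exclusion is
against the entities of the individual training fold by default; set
``against_union=True`` to exclude against all folds' training entities at
once.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from drbench.data import ResponseDataset
from drbench.harness import TunedModel, _drop_missing_features
from drbench.metrics import compute_metric_suite, normalized_metric_suite
from drbench.models import NaiveResponseModel
from drbench.splits import SplitMode

logger = logging.getLogger("drbench")


def cross_study_filter(
    train: ResponseDataset | pd.DataFrame,
    external: ResponseDataset,
    mode: SplitMode | str,
) -> tuple[ResponseDataset, int]:
    """Remove external records overlapping the training data for the mode.

    Returns the filtered external dataset and the number of removed records.
    """
    mode = SplitMode(mode)
    if isinstance(train, ResponseDataset):
        if train.measure != external.measure:
            raise ValueError(
                f"measure mismatch: training uses {train.measure!r}, external {external.measure!r}"
            )
        train_df = train.df
    else:
        train_df = train
    ext = external.df
    if mode == SplitMode.LPO:
        seen = set(zip(train_df["cell_line_id"], train_df["drug_id"]))
        keep = ~pd.Series(list(zip(ext["cell_line_id"], ext["drug_id"])), index=ext.index).isin(seen)
    elif mode == SplitMode.LCO:
        keep = ~ext["cell_line_id"].isin(set(train_df["cell_line_id"]))
    elif mode == SplitMode.LTO:
        keep = ~ext["tissue"].astype(str).isin(set(train_df["tissue"].dropna().astype(str)))
    else:
        keep = ~ext["drug_id"].isin(set(train_df["drug_id"]))
    keep = keep.to_numpy()
    removed = int((~keep).sum())
    return external.subset(keep), removed


def cross_study_evaluate(
    tuned_models: dict[tuple[str, int], TunedModel],
    externals: list[ResponseDataset],
    mode: SplitMode | str,
    features_per_dataset: dict[str, dict] | None = None,
    train_folds: dict[int, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Evaluate fold-trained models on external screens after filtering.

    ``tuned_models`` maps (model name, fold) to the trained model;
    ``train_folds`` maps fold → that fold's training table (needed both for
    overlap exclusion and for the mean-effects reference fitted on the same
    records).  Returns a long metric table with one row per
    (model, fold, external dataset, metric), including the naive
    mean-effects reference metrics on the identical filtered records.
    """
    mode = SplitMode(mode)
    if train_folds is None:
        raise ValueError("train_folds (fold -> training table) is required")
    rows = []
    for external in externals:
        feats = (features_per_dataset or {}).get(external.name)
        for (model_name, fold), tuned in sorted(tuned_models.items()):
            train_df = train_folds[fold]
            filtered, removed = cross_study_filter(train_df, external, mode)
            if len(filtered) == 0:
                logger.warning(
                    "cross-study: external %s has no records left after %s filtering of fold %d; skipped",
                    external.name, mode.value, fold,
                )
                continue
            mask = _drop_missing_features(filtered.df, tuned.spec, feats)
            if not mask.any():
                logger.warning(
                    "cross-study: no external records with features for model %s fold %d; skipped",
                    model_name, fold,
                )
                continue
            sub = filtered.df.loc[mask].reset_index(drop=True)
            y_true = filtered.values[mask]
            y_pred = np.asarray(tuned.estimator.predict(sub), dtype=float)
            if external.measure not in train_df.columns:
                raise ValueError(
                    f"training fold table lacks the measure column {external.measure!r}"
                )
            naive = NaiveResponseModel(variant="mean_effects").fit(
                train_df, train_df[external.measure].to_numpy()
            )
            y_naive = naive.predict(sub)
            plain = compute_metric_suite(y_true, y_pred)
            norm = normalized_metric_suite(y_true, y_pred, y_naive)
            ref = compute_metric_suite(y_true, y_naive)
            for tag, suite in (("model", plain), ("model_normalized", norm), ("naive_reference", ref)):
                for metric, value in suite.as_dict().items():
                    if metric == "n":
                        continue
                    rows.append(
                        {
                            "dataset": external.name,
                            "model": model_name,
                            "fold": fold,
                            "kind": tag,
                            "metric": metric,
                            "value": value,
                            "n": suite.n,
                            "n_excluded": removed,
                        }
                    )
    return pd.DataFrame(rows)
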