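"""Application-specific cross-validation splits with group disjointness.

Four hold-out designs, each matching a use case of drug response prediction:

* LPO — leave random drug/cell-line pairs out (matrix imputation);
  replicates of one pair always share a fold.
* LCO — leave cell lines out (personalized medicine: new patient).
* LTO — leave tissues out (new cancer entity).
* LDO — leave drugs out (drug design: new compound).

Folds are built by shuffling the grouping keys with the run seed and dealing
them round-robin, so fold group counts differ by at most one and the
assignment is reproducible from (dataset, mode, k, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from drbench.data import ResponseDataset


class SplitMode(str, Enum):
    LPO = "LPO"
    LCO = "LCO"
    LTO = "LTO"
    LDO = "LDO"

    @property
    def group_column(self) -> str:
        return {
            SplitMode.LPO: "__pair__",
            SplitMode.LCO: "cell_line_id",
            SplitMode.LTO: "tissue",
            SplitMode.LDO: "drug_id",
        }[self]


def _group_keys(df: pd.DataFrame, mode: SplitMode) -> pd.Series:
    """Per-record grouping key for the split mode."""
    if mode == SplitMode.LPO:
        return df["cell_line_id"].astype(str).str.cat(df["drug_id"].astype(str), sep="\x1f")
    col = mode.group_column
    if mode == SplitMode.LTO and df["tissue"].isna().any():
        raise ValueError("LTO split requires a tissue annotation for every record")
    return df[col].astype(str)


@dataclass(frozen=True)
class FoldAssignment:
    """Record-to-fold map for one cross-validation design."""

    mode: SplitMode
    k: int
    seed: int
    fold_of: np.ndarray  # fold index in [0, k) per record position

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def _deal_groups(groups: np.ndarray, k: int, rng: np.random.Generator) -> dict[str, int]:
    shuffled = groups.copy()
    rng.shuffle(shuffled)
    return {g: i % k for i, g in enumerate(shuffled)}


def make_folds(dataset: ResponseDataset, mode: SplitMode | str, k: int, seed: int) -> FoldAssignment:
    """Assign every record of ``dataset`` to one of ``k`` folds.

    Grouping keys (pairs, cell lines, tissues, or drugs depending on the
    mode) are shuffled with ``seed`` and dealt round-robin, so the key sets
    of distinct folds are disjoint by construction.
    """
    mode = SplitMode(mode)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    keys = _group_keys(dataset.df, mode)
    groups = keys.unique()
    if len(groups) < k:
        raise ValueError(
            f"{mode.value} split needs at least k={k} distinct groups, found {len(groups)}"
        )
    rng = np.random.default_rng(seed)
    fold_of_group = _deal_groups(np.sort(groups), k, rng)
    fold_of = keys.map(fold_of_group).to_numpy(dtype=np.int64)
    return FoldAssignment(mode=mode, k=k, seed=seed, fold_of=fold_of)


def make_inner_split(
    train_df: pd.DataFrame,
    mode: SplitMode | str,
    val_fraction: float = 0.1,
    seed: int = 0,
    early_stopping: bool = False,
    es_fraction: float = 0.1,
) -> tuple[np.ndarray, ...]:
    """Split an outer-training table into inner train/validation parts.

    Returns positional index arrays ``(train, validation)`` or
    ``(train, validation, es_validation)`` when ``early_stopping`` is set.
    Parts partition the input and are group-disjoint under the split mode:
    holding out a fraction of grouping keys, never a fraction of records.
    """
    mode = SplitMode(mode)
    if not 0 < val_fraction < 1:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    keys = _group_keys(train_df.reset_index(drop=True), mode)
    groups = np.sort(keys.unique())
    rng = np.random.default_rng(seed)
    shuffled = groups.copy()
    rng.shuffle(shuffled)

    n_val = max(1, int(round(val_fraction * len(groups))))
    n_es = max(1, int(round(es_fraction * (len(groups) - n_val)))) if early_stopping else 0
    if n_val + n_es >= len(groups):
        raise ValueError(
            f"val_fraction {val_fraction} leaves no training groups "
            f"({len(groups)} groups, {n_val} validation, {n_es} early-stopping)"
        )
    val_groups = set(shuffled[:n_val])
    es_groups = set(shuffled[n_val : n_val + n_es])
    is_val = keys.isin(val_groups).to_numpy()
    is_es = keys.isin(es_groups).to_numpy()
    train_idx = np.flatnonzero(~is_val & ~is_es)
    val_idx = np.flatnonzero(is_val)
    if early_stopping:
        return train_idx, val_idx, np.flatnonzero(is_es)
    return train_idx, val_idx
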