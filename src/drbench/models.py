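"""Response prediction models behind a scikit-learn estimator contract.

Every model is a :class:`sklearn.base.BaseEstimator` regressor whose ``X`` is
a pair table — a DataFrame with columns ``cell_line_id``, ``drug_id`` and
``tissue`` — and whose ``y`` is the response vector.  Feature-using models
additionally receive a ``features`` mapping (modality name → FeatureSet) as a
constructor parameter and look entity vectors up at fit/predict time, which
keeps them inductive: they can score pairs involving entities never seen
during training, as long as features exist.

The naive predictor family deliberately uses no molecular features at all.
It predicts from training response statistics alone (overall mean, per-drug
mean, per-cell-line mean, per-tissue mean, or the additive mean-effects
combination) and is the yardstick that separates genuine learning of
differential drug response from memorization of dataset biases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge

from drbench.data import FeatureSet

PAIR_COLUMNS = ("cell_line_id", "drug_id", "tissue")


def _check_pair_table(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a pair table (DataFrame with cell_line_id/drug_id columns)")
    for col in ("cell_line_id", "drug_id"):
        if col not in X.columns:
            raise ValueError(f"pair table missing column {col!r}")
    return X


class NaiveResponseModel(BaseEstimator, RegressorMixin):
    """Feature-free baseline predicting training response statistics.

    Parameters
    ----------
    variant
        ``"overall"`` — the training mean μ for every pair.
        ``"drug_mean"`` — the per-drug training mean μ_j^d, falling back to μ
        for drugs unseen in training.
        ``"cell_line_mean"`` — the per-cell-line mean μ_i^c, fallback μ.
        ``"tissue_mean"`` — the mean over training cell lines of the same
        tissue, fallback μ for unseen tissues.
        ``"mean_effects"`` — the additive combination
        ŷ_ij = μ_i^c + μ_j^d − μ, with the same per-entity fallbacks; on a
        completely crossed additive dataset this reproduces the responses
        exactly.
    """

    VARIANTS = ("overall", "drug_mean", "cell_line_mean", "tissue_mean", "mean_effects")

    def __init__(self, variant: str = "mean_effects"):
        self.variant = variant

    def fit(self, X, y):
        X = _check_pair_table(X)
        y = np.asarray(y, dtype=float)
        if self.variant not in self.VARIANTS:
            raise ValueError(f"unknown naive variant {self.variant!r}")
        if len(y) == 0:
            raise ValueError("cannot fit a naive predictor on an empty training set")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.mu_ = float(np.mean(y))
        self.cell_means_ = pd.Series(y).groupby(X["cell_line_id"].to_numpy()).mean().to_dict()
        self.drug_means_ = pd.Series(y).groupby(X["drug_id"].to_numpy()).mean().to_dict()
        if self.variant == "tissue_mean":
            if "tissue" not in X.columns or X["tissue"].isna().any():
                raise ValueError("tissue_mean variant requires tissue for all training records")
            self.tissue_means_ = (
                pd.Series(y).groupby(X["tissue"].astype(str).to_numpy()).mean().to_dict()
            )
        else:
            self.tissue_means_ = {}
        return self

    def predict(self, X) -> np.ndarray:
        X = _check_pair_table(X)
        mu = self.mu_
        if self.variant == "overall":
            return np.full(len(X), mu)
        if self.variant == "drug_mean":
            return X["drug_id"].map(self.drug_means_).fillna(mu).to_numpy(dtype=float)
        if self.variant == "cell_line_mean":
            return X["cell_line_id"].map(self.cell_means_).fillna(mu).to_numpy(dtype=float)
        if self.variant == "tissue_mean":
            return X["tissue"].astype(str).map(self.tissue_means_).fillna(mu).to_numpy(dtype=float)
        # mean_effects: unseen cell lines / drugs fall back to mu, so the
        # prediction degrades gracefully to the other entity's mean.
        cell = X["cell_line_id"].map(self.cell_means_).fillna(mu).to_numpy(dtype=float)
        drug = X["drug_id"].map(self.drug_means_).fillna(mu).to_numpy(dtype=float)
        return cell + drug - mu


class _FeatureJoinMixin:
    """Lookup of per-pair feature rows from modality-keyed FeatureSets."""

    def _design(self, X: pd.DataFrame, modalities: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Return (design matrix, row mask of pairs with complete features)."""
        feats: Mapping[str, FeatureSet] = self.features or {}
        blocks: list[np.ndarray] = []
        mask = np.ones(len(X), dtype=bool)
        for modality in modalities:
            if modality not in feats:
                raise ValueError(f"model requires modality {modality!r} but it was not provided")
            fs = feats[modality]
            if fs.is_graph:
                raise ValueError(f"modality {modality!r} is a graph; this model needs tabular views")
            id_col = "cell_line_id" if fs.entity_kind == "cell_line" else "drug_id"
            ids = X[id_col].to_numpy()
            present = np.array([e in fs.views for e in ids])
            mask &= present
            dim = fs.dim or 0
            block = np.zeros((len(X), dim))
            for pos in np.flatnonzero(present):
                block[pos] = np.asarray(fs.views[ids[pos]], dtype=float)
            blocks.append(block)
        return np.hstack(blocks) if blocks else np.empty((len(X), 0)), mask


class RidgeResponseModel(BaseEstimator, RegressorMixin, _FeatureJoinMixin):
    """L2-regularized linear model on concatenated cell-line and drug features."""

    def __init__(self, features=None, modalities=("gene_expression", "fingerprint"), alpha=1.0):
        self.features = features
        self.modalities = modalities
        self.alpha = alpha

    def fit(self, X, y):
        X = _check_pair_table(X)
        design, mask = self._design(X, self.modalities)
        if not mask.all():
            raise ValueError("training pairs with missing features must be dropped by the harness")
        self.model_ = Ridge(alpha=self.alpha).fit(design, np.asarray(y, dtype=float))
        return self

    def predict(self, X) -> np.ndarray:
        design, _ = self._design(_check_pair_table(X), self.modalities)
        return self.model_.predict(design)


class BilinearRidgeModel(BaseEstimator, RegressorMixin, _FeatureJoinMixin):
    """Ridge on main-effect blocks plus cell×drug feature products.

    Augments the concatenated cell and drug blocks with all pairwise products
    between one designated cell modality and one designated drug modality, so
    a bilinear interaction response surface u_i' W v_j is inside the model
    class.  This is the simplest learner that can capture differential drug
    response (cell-by-drug interaction) rather than only marginal effects.
    """

    def __init__(
        self,
        features=None,
        cell_modality="gene_expression",
        drug_modality="fingerprint",
        extra_modalities=(),
        alpha=1.0,
    ):
        self.features = features
        self.cell_modality = cell_modality
        self.drug_modality = drug_modality
        self.extra_modalities = extra_modalities
        self.alpha = alpha

    def _full_design(self, X: pd.DataFrame) -> np.ndarray:
        modalities = [self.cell_modality, self.drug_modality, *self.extra_modalities]
        design, mask = self._design(X, modalities)
        if not mask.all():
            raise ValueError("pairs with missing features must be dropped by the harness")
        cdim = self.features[self.cell_modality].dim
        ddim = self.features[self.drug_modality].dim
        cell, drug = design[:, :cdim], design[:, cdim : cdim + ddim]
        products = np.einsum("ni,nj->nij", cell, drug).reshape(len(X), -1)
        return np.hstack([design, products])

    def fit(self, X, y):
        X = _check_pair_table(X)
        self.model_ = Ridge(alpha=self.alpha).fit(self._full_design(X), np.asarray(y, dtype=float))
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(self._full_design(_check_pair_table(X)))


class RandomForestResponseModel(BaseEstimator, RegressorMixin, _FeatureJoinMixin):
    """Random forest on concatenated cell-line and drug features."""

    def __init__(
        self,
        features=None,
        modalities=("gene_expression", "fingerprint"),
        n_estimators=100,
        max_depth=None,
        random_state=0,
    ):
        self.features = features
        self.modalities = modalities
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_pair_table(X)
        design, mask = self._design(X, self.modalities)
        if not mask.all():
            raise ValueError("training pairs with missing features must be dropped by the harness")
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
        ).fit(design, np.asarray(y, dtype=float))
        return self

    def predict(self, X) -> np.ndarray:
        design, _ = self._design(_check_pair_table(X), self.modalities)
        return self.model_.predict(design)


class PerDrugRidgeModel(BaseEstimator, RegressorMixin, _FeatureJoinMixin):
    """One ridge regression per training drug on cell-line features.

    The classic single-drug formulation: drugs are modelled independently, so
    the model cannot predict drugs absent from training (its specs set
    ``predicts_unseen_drugs=False`` and it is excluded from LDO runs).
    Test pairs of unseen drugs fall back to that drug-free global mean.
    """

    def __init__(self, features=None, cell_modality="gene_expression", alpha=1.0):
        self.features = features
        self.cell_modality = cell_modality
        self.alpha = alpha

    def fit(self, X, y):
        X = _check_pair_table(X).reset_index(drop=True)
        y = np.asarray(y, dtype=float)
        self.mu_ = float(np.mean(y))
        self.models_ = {}
        for drug in X["drug_id"].unique():
            idx = np.flatnonzero((X["drug_id"] == drug).to_numpy())
            design, mask = self._design(X.iloc[idx].reset_index(drop=True), [self.cell_modality])
            if not mask.all():
                raise ValueError("pairs with missing features must be dropped by the harness")
            self.models_[drug] = Ridge(alpha=self.alpha).fit(design, y[idx])
        return self

    def predict(self, X) -> np.ndarray:
        X = _check_pair_table(X).reset_index(drop=True)
        out = np.full(len(X), self.mu_)
        for drug in X["drug_id"].unique():
            if drug not in self.models_:
                continue
            idx = np.flatnonzero((X["drug_id"] == drug).to_numpy())
            design, _ = self._design(X.iloc[idx].reset_index(drop=True), [self.cell_modality])
            out[idx] = self.models_[drug].predict(design)
        return out


@dataclass
class ModelSpec:
    """A model entry in a benchmark run: prototype estimator, grid, flags."""

    name: str
    estimator: BaseEstimator
    grid: dict[str, list] = field(default_factory=dict)
    required_modalities: tuple[str, ...] = ()
    single_drug: bool = False
    needs_early_stopping: bool = False
    predicts_unseen_drugs: bool = True

    def build(self, params: dict | None = None, features=None) -> BaseEstimator:
        est = clone(self.estimator)
        if params:
            est.set_params(**params)
        if features is not None and "features" in est.get_params():
            est.set_params(features=features)
        return est


def naive_specs() -> list[ModelSpec]:
    """The five naive predictors as benchmark-ready specs (empty grids)."""
    specs = []
    for variant in NaiveResponseModel.VARIANTS:
        # Per-drug means are unavailable for unseen drugs; the drug_mean
        # variant degenerates to the overall mean under LDO but stays valid.
        specs.append(ModelSpec(name=f"naive_{variant}", estimator=NaiveResponseModel(variant=variant)))
    return specs


MODEL_REGISTRY: dict[str, ModelSpec] = {spec.name: spec for spec in naive_specs()}
MODEL_REGISTRY.update(
    {
        "ridge": ModelSpec(
            name="ridge",
            estimator=RidgeResponseModel(),
            grid={"alpha": [0.1, 1.0, 10.0]},
            required_modalities=("gene_expression", "fingerprint"),
        ),
        "bilinear_ridge": ModelSpec(
            name="bilinear_ridge",
            estimator=BilinearRidgeModel(),
            grid={"alpha": [0.1, 1.0, 10.0]},
            required_modalities=("gene_expression", "fingerprint"),
        ),
        "random_forest": ModelSpec(
            name="random_forest",
            estimator=RandomForestResponseModel(),
            grid={"max_depth": [5, None]},
            required_modalities=("gene_expression", "fingerprint"),
        ),
        "per_drug_ridge": ModelSpec(
            name="per_drug_ridge",
            estimator=PerDrugRidgeModel(),
            grid={"alpha": [0.1, 1.0, 10.0]},
            required_modalities=("gene_expression",),
            single_drug=True,
            predicts_unseen_drugs=False,
        ),
    }
)
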