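import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, RegressorMixin, clone

from conftest import random_response_dataset
from drbench.data import ResponseDataset
from drbench.harness import grid_search_tune, run_cross_validation
from drbench.models import MODEL_REGISTRY, ModelSpec, NaiveResponseModel
from drbench.simulate import SyntheticConfig, generate_response_dataset


def pair(cell, drug, tissue="lung"):
    return pd.DataFrame({"cell_line_id": [cell], "drug_id": [drug], "tissue": [tissue]})


class TestNaiveFit:
    def test_three_record_means(self, tiny_train):
        m = NaiveResponseModel("mean_effects").fit(tiny_train.df, tiny_train.values)
        assert m.mu_ == pytest.approx(2.0)
        assert m.drug_means_ == pytest.approx({"dX": 1.5, "dY": 3.0})
        assert m.cell_means_ == pytest.approx({"c1": 2.0, "c2": 2.0})

    def test_constant_training_values(self):
        df = pd.DataFrame(
            {"cell_line_id": ["a", "b"], "drug_id": ["d", "e"], "tissue": ["t", "t"]}
        )
        for variant in NaiveResponseModel.VARIANTS:
            m = NaiveResponseModel(variant).fit(df, [3.0, 3.0])
            np.testing.assert_allclose(m.predict(pair("zz", "zz", "t")), [3.0])

    def test_tissue_means_are_cell_line_group_means(self, tiny_train):
        m = NaiveResponseModel("tissue_mean").fit(tiny_train.df, tiny_train.values)
        # lung holds c1's records (1.0, 3.0), skin holds c2's (2.0)
        assert m.tissue_means_ == pytest.approx({"lung": 2.0, "skin": 2.0})

    def test_empty_train_errors(self):
        with pytest.raises(ValueError, match="empty"):
            NaiveResponseModel().fit(pair("c", "d").iloc[:0], [])


class TestNaivePredict:
    @pytest.fixture
    def fitted(self, tiny_train):
        return NaiveResponseModel("mean_effects").fit(tiny_train.df, tiny_train.values)

    def test_mean_effects_equation(self, fitted):
        # mu_c2 + mu_dY - mu = 2.0 + 3.0 - 2.0
        assert fitted.predict(pair("c2", "dY"))[0] == pytest.approx(3.0)

    def test_unseen_drug_falls_back_to_cell_mean(self, fitted):
        assert fitted.predict(pair("c1", "dZ"))[0] == pytest.approx(2.0)

    def test_unseen_both_falls_back_to_mu(self, fitted):
        assert fitted.predict(pair("cX", "dZ"))[0] == pytest.approx(2.0)

    def test_sklearn_clone_contract(self):
        m = NaiveResponseModel("drug_mean")
        assert clone(m).get_params() == m.get_params()


class TestMeanEffectsExactness:
    def test_exact_on_complete_additive_data(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(0, 2, 7)
        rows = [
            {"cell_line_id": f"c{i}", "drug_id": f"d{j}", "tissue": "t",
             "y": 5.0 + a[i] + b[j]}
            for i in range(12) for j in range(7)
        ]
        df = pd.DataFrame(rows)
        m = NaiveResponseModel("mean_effects").fit(df, df["y"])
        np.testing.assert_allclose(m.predict(df), df["y"], atol=1e-12)

    def test_matches_bruteforce_oracle_on_random_datasets(self):
        """Eq.-style two-way means computed by explicit loops agree <= 1e-12."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            ds = random_response_dataset(rng)
            df, y = ds.df, ds.values
            m = NaiveResponseModel("mean_effects").fit(df, y)
            pred = m.predict(df)
            cells, drugs = list(df["cell_line_id"]), list(df["drug_id"])
            yl = list(y)
            mu = sum(yl) / len(yl)
            for idx in range(len(df)):
                cm_vals = [yi for ci, yi in zip(cells, yl) if ci == cells[idx]]
                dm_vals = [yi for di, yi in zip(drugs, yl) if di == drugs[idx]]
                oracle = sum(cm_vals) / len(cm_vals) + sum(dm_vals) / len(dm_vals) - mu
                assert abs(pred[idx] - oracle) <= 1e-12


class _OffsetModel(BaseEstimator, RegressorMixin):
    """Toy learner whose validation error is a known function of `offset`."""

    def __init__(self, offset=0.0, unused=0):
        self.offset = offset
        self.unused = unused

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_ + self.offset)


class TestGridSearch:
    def setup_method(self):
        rng = np.random.default_rng(9)
        self.ds = random_response_dataset(rng, n_cells=20, n_drugs=6, n_records=120)

    def test_single_configuration_returned(self):
        spec = ModelSpec("toy", _OffsetModel(), grid={"offset": [0.7]})
        tuned = grid_search_tune(spec, self.ds.df, self.ds.values, "LCO", seed=0)
        assert tuned.params == {"offset": 0.7}

    def test_lower_validation_rmse_wins(self):
        spec = ModelSpec("toy", _OffsetModel(), grid={"offset": [5.0, 0.0]})
        tuned = grid_search_tune(spec, self.ds.df, self.ds.values, "LCO", seed=0)
        assert tuned.params == {"offset": 0.0}

    def test_tie_broken_by_grid_order(self):
        spec = ModelSpec("toy", _OffsetModel(), grid={"offset": [0.3], "unused": [1, 2]})
        tuned = grid_search_tune(spec, self.ds.df, self.ds.values, "LCO", seed=0)
        assert tuned.params["unused"] == 1

    def test_refit_uses_full_training_set(self):
        spec = ModelSpec("toy", _OffsetModel(), grid={"offset": [0.0, 1.0]})
        tuned = grid_search_tune(spec, self.ds.df, self.ds.values, "LPO", seed=1)
        assert tuned.estimator.mean_ == pytest.approx(float(self.ds.values.mean()))


class TestRunCrossValidation:
    def test_every_test_record_predicted_once(self, tiny_train):
        rng = np.random.default_rng(5)
        ds = random_response_dataset(rng, n_cells=12, n_drugs=6, n_records=80)
        specs = [MODEL_REGISTRY["naive_overall"], MODEL_REGISTRY["naive_mean_effects"]]
        pred = run_cross_validation(ds, specs, "LCO", k=3, seed=0)
        assert len(pred) == 2 * len(ds)
        per_model = pred.groupby("model").size()
        assert (per_model == len(ds)).all()

    def test_ldo_mean_effects_reduces_to_cell_mean_fallback(self):
        rng = np.random.default_rng(6)
        ds = random_response_dataset(rng, n_cells=10, n_drugs=8, n_records=70)
        pred = run_cross_validation(
            ds, [MODEL_REGISTRY["naive_mean_effects"], MODEL_REGISTRY["naive_cell_line_mean"]],
            "LDO", k=4, seed=0,
        )
        wide = pred.pivot_table(
            index=["fold", "cell_line_id", "drug_id"], columns="model", values="y_pred",
            aggfunc="first",
        )
        np.testing.assert_allclose(
            wide["naive_mean_effects"], wide["naive_cell_line_mean"], atol=1e-12
        )

    def test_model_without_unseen_drug_support_skipped_under_ldo(self):
        rng = np.random.default_rng(8)
        ds = random_response_dataset(rng, n_cells=10, n_drugs=8, n_records=60)
        no_ldo = ModelSpec("no_ldo", NaiveResponseModel("overall"), predicts_unseen_drugs=False)
        with pytest.warns(UserWarning, match="unseen drugs"):
            pred = run_cross_validation(
                ds, [no_ldo, MODEL_REGISTRY["naive_overall"]], "LDO", k=3, seed=0
            )
        assert set(pred["model"]) == {"naive_overall"}

    def test_same_seed_reproduces_table(self):
        rng = np.random.default_rng(10)
        ds = random_response_dataset(rng, n_cells=10, n_drugs=6, n_records=60)
        spec = [MODEL_REGISTRY["naive_drug_mean"]]
        a = run_cross_validation(ds, spec, "LPO", k=3, seed=7)
        b = run_cross_validation(ds, spec, "LPO", k=3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_leakage_guard_trips_on_corrupted_folds(self):
        from drbench.harness import TunedModel, _assert_no_leakage
        from drbench.splits import SplitMode

        tuned = TunedModel(
            spec=MODEL_REGISTRY["naive_overall"], params={}, estimator=None, fold=0,
            validation_rmse=0.0, train_cell_lines=frozenset({"c1"}),
            train_drugs=frozenset({"d1"}), train_tissues=frozenset(),
            train_pairs=frozenset({("c1", "d1")}),
        )
        test_df = pd.DataFrame({"cell_line_id": ["c1"], "drug_id": ["d9"], "tissue": ["t"]})
        with pytest.raises(RuntimeError, match="leakage"):
            _assert_no_leakage(tuned, test_df, SplitMode.LCO)

    def test_fixed_measure_shared_by_all_models(self):
        cfg = SyntheticConfig(n_cell_lines=15, n_drugs=8, completeness=0.8, seed=2)
        ds, _ = generate_response_dataset(cfg)
        pred = run_cross_validation(
            ds, [MODEL_REGISTRY["naive_overall"], MODEL_REGISTRY["naive_drug_mean"]],
            "LPO", k=3, seed=2,
        )
        merged = pred.pivot_table(
            index=["fold", "cell_line_id", "drug_id"], columns="model", values="y_true",
            aggfunc="first",
        ).dropna()
        np.testing.assert_allclose(merged.iloc[:, 0], merged.iloc[:, 1])
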