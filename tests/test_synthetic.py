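import numpy as np
import pandas as pd
import pytest

from drbench.harness import run_cross_validation
from drbench.metrics import per_fold_metric_table
from drbench.models import MODEL_REGISTRY, NaiveResponseModel
from drbench.simulate import (
    SyntheticConfig,
    generate_benchmark,
    generate_features,
    generate_raw_viability,
    generate_response_dataset,
)


class TestResponseGenerator:
    def test_additive_complete_data_reproduced_by_mean_effects(self):
        cfg = SyntheticConfig(
            n_cell_lines=20, n_drugs=10, completeness=1.0,
            sd_interaction=0.0, sd_noise=0.0, seed=1,
        )
        ds, _ = generate_response_dataset(cfg)
        m = NaiveResponseModel("mean_effects").fit(ds.df, ds.values)
        np.testing.assert_allclose(m.predict(ds.df), ds.values, atol=1e-10)

    def test_same_seed_identical_dataset(self):
        cfg = SyntheticConfig(n_cell_lines=15, n_drugs=8, seed=7)
        a, _ = generate_response_dataset(cfg)
        b, _ = generate_response_dataset(cfg)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_components_reconstruct_response(self):
        cfg = SyntheticConfig(n_cell_lines=12, n_drugs=6, completeness=0.9, seed=3)
        ds, comp = generate_response_dataset(cfg)
        ci, dj = comp["record_cell_index"], comp["record_drug_index"]
        cells, drugs = np.array(comp["cells"]), np.array(comp["drugs"])
        rebuilt = (
            comp["mu0"]
            + np.array([comp["cell_effects"][c] for c in cells[ci]])
            + np.array([comp["drug_effects"][d] for d in drugs[dj]])
            + np.array([comp["tissue_effects"][comp["tissue_of"][c]] for c in cells[ci]])
            + comp["interaction"][ci, dj]
            + comp["noise"]
        )
        np.testing.assert_allclose(rebuilt, ds.values, atol=1e-12)

    def test_every_entity_has_records(self):
        cfg = SyntheticConfig(n_cell_lines=30, n_drugs=15, completeness=0.15, seed=5)
        ds, _ = generate_response_dataset(cfg)
        assert len(ds.cell_lines) == 30
        assert len(ds.drugs) == 15

    def test_empirical_variance_shares_match_configuration(self):
        """At 300x150 each realized component share is within 0.02 of its dial."""
        cfg = SyntheticConfig(n_cell_lines=300, n_drugs=150, completeness=1.0, seed=9)
        ds, comp = generate_response_dataset(cfg)
        ci, dj = comp["record_cell_index"], comp["record_drug_index"]
        cells, drugs = np.array(comp["cells"]), np.array(comp["drugs"])
        total = ds.values.var()
        shares = {
            "drug": np.array([comp["drug_effects"][d] for d in drugs[dj]]).var() / total,
            "cell": np.array([comp["cell_effects"][c] for c in cells[ci]]).var() / total,
            "interaction": comp["interaction"][ci, dj].var() / total,
            "noise": comp["noise"].var() / total,
        }
        cfg_total = cfg.total_variance
        assert shares["drug"] == pytest.approx(cfg.sd_drug**2 / cfg_total, abs=0.02)
        assert shares["cell"] == pytest.approx(cfg.sd_cell**2 / cfg_total, abs=0.02)
        assert shares["interaction"] == pytest.approx(cfg.sd_interaction**2 / cfg_total, abs=0.02)
        assert shares["noise"] == pytest.approx(cfg.sd_noise**2 / cfg_total, abs=0.02)


class TestFeatures:
    def make(self, **kw):
        cfg = SyntheticConfig(n_cell_lines=25, n_drugs=12, seed=4, **kw)
        ds, comp = generate_response_dataset(cfg)
        return cfg, ds, comp, generate_features(cfg, comp)

    def test_declared_dimensions(self):
        cfg, _, _, feats = self.make(feature_dim=11)
        assert feats["gene_expression"].dim == 11
        assert feats["fingerprint"].dim == 11
        assert feats["drug_graph"].is_graph

    def test_informative_block_carries_cell_effect(self):
        _, _, comp, feats = self.make(informative_fraction=0.5)
        col0 = np.array([feats["gene_expression"].views[c][0] for c in comp["cells"]])
        eff = np.array([comp["cell_effects"][c] for c in comp["cells"]])
        np.testing.assert_allclose(col0, eff)

    def test_zero_informative_fraction_gives_pure_noise(self):
        _, _, comp, feats = self.make(informative_fraction=0.0)
        col = np.array([feats["gene_expression"].views[c][0] for c in comp["cells"]])
        eff = np.array([comp["cell_effects"][c] for c in comp["cells"]])
        assert abs(np.corrcoef(col, eff)[0, 1]) < 0.5  # no constructed link

    def test_graph_modality_covers_all_drugs(self):
        _, _, comp, feats = self.make()
        assert set(feats["drug_graph"].views) == set(comp["drugs"])


class TestSimpsonConstruction:
    def test_global_vs_per_drug_pearson(self):
        """Dominant drug effects: global correlation high, within-drug ~ zero."""
        from scipy import stats

        from drbench.metrics import stratified_metrics

        cfg = SyntheticConfig(
            n_cell_lines=2000, n_drugs=50, completeness=1.0,
            sd_drug=np.sqrt(0.9), sd_cell=0.0, sd_tissue=0.0,
            sd_interaction=0.0, sd_noise=np.sqrt(0.1), seed=5,
        )
        ds, _ = generate_response_dataset(cfg)
        pred = run_cross_validation(
            ds, [MODEL_REGISTRY["naive_drug_mean"]], "LPO", k=10, seed=5
        )
        glob = stats.pearsonr(pred["y_true"], pred["y_pred"])[0]
        per_drug = stratified_metrics(pred, by="drug")["pearson"]
        assert glob > 0.9
        assert -0.1 <= per_drug.mean() <= 0.1


class TestRawViability:
    DOSES = np.logspace(-2, 2, 8)

    def test_noiseless_recovery_through_curve_module(self):
        from drbench.curves import fit_viability_table

        raw, truth = generate_raw_viability(10, self.DOSES, noise_sd=0.0, seed=6)
        fitted = fit_viability_table(raw)
        merged = fitted.merge(truth, on=["cell_line_id", "drug_id"], suffixes=("_f", "_t"))
        assert (merged["pEC50_f"] - merged["pEC50_t"]).abs().max() < 1e-3

    def test_flat_curves_give_large_p_values(self):
        from drbench.curves import fit_viability_table

        raw, _ = generate_raw_viability(20, self.DOSES, noise_sd=0.05, seed=8, flat=True)
        fitted = fit_viability_table(raw)
        # under the flat null, small p-values are rare
        assert (fitted["p_value"] < 0.05).mean() <= 0.15
        assert fitted["p_value"].median() > 0.2

    def test_same_seed_identical_table(self):
        a, _ = generate_raw_viability(5, self.DOSES, seed=9)
        b, _ = generate_raw_viability(5, self.DOSES, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unsorted_doses_rejected(self):
        with pytest.raises(ValueError):
            generate_raw_viability(2, [1.0, 0.5], seed=0)


class TestEndToEndSignalRecovery:
    def test_informative_features_enable_interaction_learning(self):
        """A bilinear learner recovers interaction signal on LCO; the naive
        mean-effects model cannot (normalized R2 near zero)."""
        from drbench.models import BilinearRidgeModel, ModelSpec

        cfg = SyntheticConfig(
            n_cell_lines=80, n_drugs=40, completeness=0.6, n_tissues=4,
            sd_drug=np.sqrt(0.3), sd_cell=np.sqrt(0.1), sd_tissue=0.0,
            sd_interaction=np.sqrt(0.45), sd_noise=np.sqrt(0.15),
            feature_dim=8, latent_dim=3, informative_fraction=0.5, seed=21,
        )
        ds, feats, _ = generate_benchmark(cfg)
        spec = ModelSpec(
            "bilinear", BilinearRidgeModel(alpha=1.0),
            required_modalities=("gene_expression", "fingerprint"),
        )
        pred = run_cross_validation(
            ds, [spec, MODEL_REGISTRY["naive_mean_effects"]], "LCO", k=5, seed=21,
            features=feats,
        )
        mt = per_fold_metric_table(pred)
        norm_r2 = mt[(mt.metric == "r2") & (mt.normalized)]
        bilinear = norm_r2[norm_r2.model == "bilinear"]["value"].mean()
        naive = norm_r2[norm_r2.model == "naive_mean_effects"]["value"].mean()
        assert bilinear > 0.5
        assert naive <= 0.05
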