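"""Run configuration, output writing, and the static run summary.

A benchmark run is described by a YAML configuration (dataset paths or a
synthetic block, the model list with grids, split mode(s), k, seed, and
optional ablation / cross-study / robustness blocks).  Outputs are plain
CSVs plus a text summary; stored metric values are never clipped — the
rendering of negative normalized R² as zero happens only in the summary.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import drbench
from drbench.ablation import ablation_delta, randomize_features
from drbench.data import ResponseDataset, filter_by_curve_quality, load_feature_matrix, load_response_table
from drbench.harness import run_cross_validation
from drbench.metrics import per_fold_metric_table, stratified_metrics
from drbench.models import MODEL_REGISTRY, ModelSpec
from drbench.ranking import compare_models
from drbench.simulate import SyntheticConfig, generate_benchmark
from drbench.splits import SplitMode

logger = logging.getLogger("drbench")

_DEFAULTS = {"mode": "LCO", "k": 5, "seed": 0, "quality_alpha": None, "val_fraction": 0.1}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    """Check a run configuration up front; raise listing every violation."""
    problems = []
    merged = {**_DEFAULTS, **cfg}
    if "models" not in merged or not merged["models"]:
        problems.append("config needs a non-empty 'models' list")
    else:
        unknown = [m for m in merged["models"] if m not in MODEL_REGISTRY]
        if unknown:
            problems.append(f"unknown model(s): {', '.join(unknown)} "
                            f"(available: {', '.join(sorted(MODEL_REGISTRY))})")
    modes = merged.get("modes") or [merged["mode"]]
    for m in modes:
        try:
            SplitMode(m)
        except ValueError:
            problems.append(f"unknown split mode {m!r}")
    merged["modes"] = [SplitMode(m) for m in modes if m in SplitMode.__members__]
    if not isinstance(merged["k"], int) or merged["k"] < 2:
        problems.append(f"k must be an integer >= 2, got {merged['k']!r}")
    has_synth = "synthetic" in merged
    has_path = "response_path" in merged
    if has_synth == has_path:
        problems.append("config needs exactly one of 'synthetic' or 'response_path'")
    if problems:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))
    return merged


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out_dir / "run.log"),
    ]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in logger.handlers:
        h.setFormatter(fmt)


def _build_inputs(cfg: dict):
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        syn.setdefault("seed", cfg["seed"])
        config = SyntheticConfig(**syn)
        dataset, features, _ = generate_benchmark(config)
        logger.info("generated synthetic dataset: %d records, %d cell lines, %d drugs",
                    len(dataset), config.n_cell_lines, config.n_drugs)
    else:
        dataset = load_response_table(cfg["response_path"], measure=cfg.get("measure", "LN_IC50"))
        if dataset.n_dropped:
            logger.info("dropped %d records with missing response values", dataset.n_dropped)
        features = {}
        for block in cfg.get("features", []):
            fs = load_feature_matrix(block["path"], block["modality"], block["entity_kind"])
            features[fs.modality] = fs
    if cfg.get("quality_alpha") is not None:
        before = len(dataset)
        dataset = filter_by_curve_quality(dataset, cfg["quality_alpha"])
        logger.info("quality filter alpha=%s removed %d records",
                    cfg["quality_alpha"], before - len(dataset))
    return dataset, features


def _model_specs(cfg: dict) -> list[ModelSpec]:
    specs = []
    for name in cfg["models"]:
        spec = MODEL_REGISTRY[name]
        grid_override = (cfg.get("grids") or {}).get(name)
        if grid_override:
            spec = ModelSpec(**{**asdict_spec(spec), "grid": grid_override})
        specs.append(spec)
    return specs


def asdict_spec(spec: ModelSpec) -> dict:
    return {
        "name": spec.name, "estimator": spec.estimator, "grid": spec.grid,
        "required_modalities": spec.required_modalities, "single_drug": spec.single_drug,
        "needs_early_stopping": spec.needs_early_stopping,
        "predicts_unseen_drugs": spec.predicts_unseen_drugs,
    }


def run_from_config(config: dict | str | Path, out_dir: str | Path) -> Path:
    """Execute a full benchmark run and write the output tree.

    Stages: splitting → tuning → prediction → metrics → rank statistics,
    plus ablation when the config requests it.  The resolved configuration
    (including defaults and seeds) is echoed into the output directory so a
    rerun reproduces every file.
    """
    cfg = load_config(config) if not isinstance(config, dict) else validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    resolved = {k: (v if not isinstance(v, (SplitMode,)) else v.value) for k, v in cfg.items()}
    resolved["modes"] = [m.value for m in cfg["modes"]]
    resolved["tool_version"] = drbench.__version__
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)

    dataset, features = _build_inputs(cfg)
    specs = _model_specs(cfg)

    all_pred, all_metrics, all_strat, rank_rows, cd_rows, abl_rows = [], [], [], [], [], []
    for mode in cfg["modes"]:
        logger.info("running %s with k=%d seed=%d", mode.value, cfg["k"], cfg["seed"])
        predictions = run_cross_validation(
            dataset, specs, mode, k=cfg["k"], seed=cfg["seed"], features=features,
            val_fraction=cfg["val_fraction"],
        )
        predictions.insert(0, "mode", mode.value)
        all_pred.append(predictions)

        metric_table = per_fold_metric_table(predictions)
        metric_table.insert(0, "mode", mode.value)
        all_metrics.append(metric_table)

        for by in ("drug", "cell_line"):
            strat = stratified_metrics(predictions, by=by)
            strat.insert(0, "mode", mode.value)
            all_strat.append(strat)

        if predictions["model"].nunique() >= 2 and cfg["k"] >= 2:
            cmp = compare_models(metric_table[metric_table["mode"] == mode.value])
            rank_rows.append(
                pd.DataFrame(
                    {
                        "mode": mode.value,
                        "friedman_q": cmp["friedman_q"],
                        "friedman_p": cmp["friedman_p"],
                        "omnibus_significant": cmp["omnibus_significant"],
                        "model_a": cmp["posthoc"]["model_a"],
                        "model_b": cmp["posthoc"]["model_b"],
                        "p_raw": cmp["posthoc"]["p_raw"],
                        "p_adjusted": cmp["posthoc"]["p_adjusted"],
                    }
                )
            )
            for gi, grp in enumerate(cmp["cd_groups"]):
                for model in grp:
                    cd_rows.append(
                        {"mode": mode.value, "group": gi, "model": model,
                         "mean_rank": cmp["mean_ranks"][model]}
                    )

        for block in cfg.get("ablation", []):
            abl_rows.extend(_run_ablation(block, dataset, specs, mode, cfg, features,
                                          metric_table))

    outputs = {
        "predictions.csv": pd.concat(all_pred, ignore_index=True),
        "metrics_per_fold.csv": pd.concat(all_metrics, ignore_index=True),
        "metrics_stratified.csv": pd.concat(all_strat, ignore_index=True),
    }
    if rank_rows:
        outputs["friedman_conover.csv"] = pd.concat(rank_rows, ignore_index=True)
        outputs["cd_groups.csv"] = pd.DataFrame(cd_rows)
    if abl_rows:
        outputs["ablation.csv"] = pd.DataFrame(abl_rows)
    write_outputs(outputs, out)
    (out / "summary.txt").write_text(render_summary(outputs))
    logger.info("run complete: %s", out)
    return out


def _run_ablation(block, dataset, specs, mode, cfg, features, metric_table):
    """Retrain the named model with one modality randomized; collect deltas."""
    model_name, modality, how = block["model"], block["modality"], block.get("how", "permute")
    spec = next((s for s in specs if s.name == model_name), None)
    if spec is None:
        logger.warning("ablation block names unknown model %s; skipped", model_name)
        return []
    randomized = randomize_features(features, modality, how, seed=cfg["seed"] + 997)
    ablated_pred = run_cross_validation(
        dataset, [spec], mode, k=cfg["k"], seed=cfg["seed"], features=randomized,
        val_fraction=cfg["val_fraction"],
    )
    abl_metrics = per_fold_metric_table(ablated_pred)

    def fold_values(table, normalized):
        sub = table[(table["model"] == model_name) & (table["metric"] == "r2")
                    & (table["normalized"] == normalized)]
        return sub.sort_values("fold")["value"].to_numpy()

    rows = []
    for normalized in (False, True):
        base = fold_values(metric_table, normalized)
        abl = fold_values(abl_metrics, normalized)
        res = ablation_delta(base, abl, model=model_name, mode=how, modality=modality)
        rows.append(
            {"mode": mode.value, "model": model_name, "modality": modality, "how": how,
             "normalized": normalized, "delta_mean": res.delta_mean,
             "ci_low": res.ci_low, "ci_high": res.ci_high,
             "unperturbed_mean": float(np.mean(base)), "ablated_mean": float(np.mean(abl))}
        )
    return rows


def write_outputs(outputs: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write every result table as CSV (values stored unclipped)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in outputs.items():
        path = out / name
        df.to_csv(path, index=False)
        paths.append(path)
    return paths


def render_summary(outputs: dict[str, pd.DataFrame]) -> str:
    """Static text summary; negative (normalized) R² rendered as 0 here only."""
    lines = [f"drbench {drbench.__version__} run summary", ""]
    metrics = outputs.get("metrics_per_fold.csv")
    if metrics is not None and len(metrics):
        sub = metrics[metrics["metric"].isin(["r2", "pearson", "mse"])]
        agg = (
            sub.groupby(["mode", "model", "metric", "normalized"])["value"]
            .mean()
            .reset_index()
        )
        clipped = agg["metric"] == "r2"
        agg.loc[clipped, "value"] = agg.loc[clipped, "value"].clip(lower=0.0)
        wide = agg.pivot_table(
            index=["mode", "model"], columns=["metric", "normalized"], values="value"
        ).round(3)
        lines += ["Mean per-fold metrics (R2 clipped at 0 for display):",
                  wide.to_string(), ""]
    fc = outputs.get("friedman_conover.csv")
    if fc is not None and len(fc):
        for mode, grp in fc.groupby("mode"):
            q, p = grp["friedman_q"].iloc[0], grp["friedman_p"].iloc[0]
            flag = "" if grp["omnibus_significant"].iloc[0] else "  [omnibus not significant]"
            lines.append(f"{mode}: Friedman Q={q:.3f}, p={p:.4g}{flag}")
        lines.append("")
    cd = outputs.get("cd_groups.csv")
    if cd is not None and len(cd):
        lines.append("Critical-difference groups (models not significantly different):")
        for (mode, gi), grp in cd.groupby(["mode", "group"]):
            members = ", ".join(
                f"{r.model} ({r.mean_rank:.2f})" for r in grp.itertuples()
            )
            lines.append(f"  {mode} bar {gi}: {members}")
        lines.append("")
    abl = outputs.get("ablation.csv")
    if abl is not None and len(abl):
        lines.append("Ablation deltas (R2, ablated - unperturbed, mean [95% band]):")
        for r in abl.itertuples():
            tag = "normalized " if r.normalized else ""
            lines.append(
                f"  {r.mode} {r.model} {r.modality} ({r.how}, {tag}r2): "
                f"{r.delta_mean:+.3f} [{r.ci_low:+.3f}, {r.ci_high:+.3f}]"
            )
        lines.append("")
    return "\n".join(lines)
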