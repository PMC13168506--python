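"""Feature-ablation randomizers and robustness refits.

Three null operators probe what a model actually learns from a feature
modality, each destroying a different level of structure:

* :func:`permute_modality` — reassigns whole feature vectors across entities,
  breaking the entity–feature link while keeping the vector multiset intact.
* :func:`moment_preserving_randomize` — replaces each tabular feature column
  with Gaussian draws matching that column's sample mean and standard
  deviation, destroying everything except first and second moments; a model
  that survives this was only ever using summary statistics.
* :func:`degree_preserving_shuffle` — rewires a graph by double-edge swaps
  that preserve every node degree, the standard configuration-model null.

An ablation is only meaningful when the model is retrained from scratch on
the randomized features; :func:`ablation_delta` just does the paired
per-fold arithmetic (delta = ablated − unperturbed, ±1.96·SEM band).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from drbench.data import FeatureSet


def permute_modality(features: FeatureSet, seed: int) -> FeatureSet:
    """Uniformly permute the entity → feature-view assignment."""
    entities = list(features.views.keys())
    if len(entities) < 2:
        raise ValueError("permutation needs at least 2 entities")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(entities))
    views = {entities[i]: features.views[entities[perm[i]]] for i in range(len(entities))}
    return FeatureSet(modality=features.modality, entity_kind=features.entity_kind, views=views)


def moment_preserving_randomize(features: FeatureSet, seed: int, per_entity: bool = False) -> FeatureSet:
    """Replace tabular features by Gaussians with matched column moments.

    By default moments are matched per feature column across entities (each
    column keeps its sample mean and sample standard deviation); with
    ``per_entity`` the moments of each entity's vector are matched instead.
    A zero-variance column is reproduced exactly.
    """
    if features.is_graph:
        raise ValueError("moment-preserving randomization applies to tabular modalities; "
                         "use degree_preserving_shuffle for graphs")
    entities = list(features.views.keys())
    if len(entities) < 2:
        raise ValueError("randomization needs at least 2 entities")
    rng = np.random.default_rng(seed)
    mat = features.matrix(entities)
    if per_entity:
        mean = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True) if mat.shape[1] > 1 else np.zeros_like(mean)
    else:
        mean = mat.mean(axis=0, keepdims=True)
        sd = mat.std(axis=0, ddof=1, keepdims=True)
    new = mean + sd * rng.standard_normal(mat.shape)
    views = {e: new[i] for i, e in enumerate(entities)}
    return FeatureSet(modality=features.modality, entity_kind=features.entity_kind, views=views)


def degree_preserving_shuffle(graph: nx.Graph, seed: int, n_swaps: int | None = None) -> nx.Graph:
    """Rewire a simple graph by double-edge swaps preserving all degrees.

    Candidate swaps (a−b, c−d) → (a−d, c−b) are drawn at random and rejected
    if they would create a self-loop or a multi-edge.  ``n_swaps`` counts
    attempted swaps (default 10 × edge count, a standard mixing heuristic).
    Graphs with no legal swap (paths of length 2, stars) come back unchanged.
    """
    g = graph.copy()
    edges = list(g.edges)
    m = len(edges)
    if m < 2:
        return g
    if n_swaps is None:
        n_swaps = 10 * m
    rng = np.random.default_rng(seed)
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:  # also consider the crossed pairing
            c, d = d, c
        # proposed replacement: (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i], edges[j] = (a, d), (c, b)
    return g


@dataclass(frozen=True)
class AblationResult:
    """Paired per-fold performance change after one randomization."""

    model: str
    mode: str  # which randomizer was applied
    modality: str
    unperturbed: tuple[float, ...]
    ablated: tuple[float, ...]
    delta_mean: float
    ci_low: float
    ci_high: float


def ablation_delta(
    unperturbed_r2,
    ablated_r2,
    model: str = "",
    mode: str = "",
    modality: str = "",
) -> AblationResult:
    """Per-fold delta (ablated − unperturbed) with a ±1.96·SEM band.

    Negative deltas mean the randomization hurt the model, i.e. the modality
    carried signal.  The caller must have *retrained* the model on the
    randomized features; merely re-predicting with the old fit understates
    what a model could still extract from the surviving structure.
    """
    a = np.asarray(unperturbed_r2, dtype=float)
    b = np.asarray(ablated_r2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unperturbed and ablated values must be fold-paired")
    if len(a) < 2:
        raise ValueError("ablation delta needs at least 2 folds")
    d = b - a
    mean = float(d.mean())
    sem = float(d.std(ddof=1) / np.sqrt(len(d)))
    return AblationResult(
        model=model,
        mode=mode,
        modality=modality,
        unperturbed=tuple(a),
        ablated=tuple(b),
        delta_mean=mean,
        ci_low=mean - 1.96 * sem,
        ci_high=mean + 1.96 * sem,
    )


def randomize_features(
    features: dict[str, FeatureSet], modality: str, how: str, seed: int
) -> dict[str, FeatureSet]:
    """Copy of a feature collection with one modality randomized.

    ``how`` is ``"permute"``, ``"moments"`` (tabular) or ``"degree"``
    (graph; every entity's graph is rewired independently).
    """
    if modality not in features:
        raise ValueError(f"unknown modality {modality!r}")
    out = dict(features)
    fs = features[modality]
    if how == "permute":
        out[modality] = permute_modality(fs, seed)
    elif how == "moments":
        out[modality] = moment_preserving_randomize(fs, seed)
    elif how == "degree":
        if not fs.is_graph:
            raise ValueError("degree-preserving shuffle needs a graph modality")
        views = {
            e: degree_preserving_shuffle(g, seed=seed + i)
            for i, (e, g) in enumerate(fs.views.items())
        }
        out[modality] = FeatureSet(modality=fs.modality, entity_kind=fs.entity_kind, views=views)
    else:
        raise ValueError(f"unknown randomization {how!r}")
    return out


def robustness_refit(spec, train_df, y, test_df, y_test, features=None, seeds=(0, 1, 2)):
    """Refit one model with different initialization seeds; report the spread.

    Returns a dict with per-seed test MSEs and their min/max/sd.  A
    deterministic model yields zero spread, which is a result, not an error.
    """
    from drbench.metrics import compute_metric_suite

    mses = []
    for s in seeds:
        est = spec.build(features=features)
        if "random_state" in est.get_params():
            est.set_params(random_state=int(s))
        est.fit(train_df.reset_index(drop=True), y)
        suite = compute_metric_suite(y_test, est.predict(test_df.reset_index(drop=True)))
        mses.append(suite.mse)
    arr = np.asarray(mses)
    return {
        "seeds": tuple(int(s) for s in seeds),
        "mse": tuple(arr),
        "min": float(arr.min()),
        "max": float(arr.max()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    }
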