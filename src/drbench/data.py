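"""Domain containers and delimited-text IO for response and feature tables.

A response dataset is a long-format table of measured drug responses keyed by
(cell line, drug).  Multiple rows for the same pair are replicates and are
kept distinguishable through their row index.  A feature set maps entity ids
(cell lines or drugs) of one modality either to fixed-length numeric vectors
or to simple undirected graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: Measures with a fixed meaning; any other name is accepted as custom.
KNOWN_MEASURES = ("LN_IC50", "IC50", "EC50", "pEC50", "AUC")

RESPONSE_COLUMNS = ("cell_line_id", "drug_id", "tissue", "quality_p")


class SchemaError(ValueError):
    """A delimited input file does not match the expected schema."""


@dataclass
class ResponseDataset:
    """Long-format drug response records with exactly one response measure.

    Parameters
    ----------
    df
        Table with columns ``cell_line_id``, ``drug_id``, the measure column,
        and optionally ``tissue`` and ``quality_p``.  Row order is the record
        order and is stable under round-trip through CSV.
    measure
        Name of the response measure column (e.g. ``LN_IC50``).
    name
        Dataset label used in outputs.
    """

    df: pd.DataFrame
    measure: str = "LN_IC50"
    name: str = "dataset"
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in ("cell_line_id", "drug_id", self.measure) if c not in self.df.columns]
        if missing:
            raise SchemaError(f"response table missing required column(s): {', '.join(missing)}")
        if "tissue" not in self.df.columns:
            self.df = self.df.assign(tissue=pd.NA)
        vals = pd.to_numeric(self.df[self.measure], errors="coerce")
        keep = np.isfinite(vals.to_numpy(dtype=float, na_value=np.nan))
        self.n_dropped += int((~keep).sum())
        if not keep.all():
            self.df = self.df.loc[keep]
        self.df = self.df.reset_index(drop=True)
        self.df[self.measure] = self.df[self.measure].astype(float)
        self.df["cell_line_id"] = self.df["cell_line_id"].astype(str)
        self.df["drug_id"] = self.df["drug_id"].astype(str)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        return self.df[self.measure].to_numpy()

    @property
    def cell_lines(self) -> np.ndarray:
        return self.df["cell_line_id"].unique()

    @property
    def drugs(self) -> np.ndarray:
        return self.df["drug_id"].unique()

    @property
    def pairs(self) -> pd.Series:
        """Pair-grouping key: one string per record, shared by replicates."""
        return self.df["cell_line_id"].str.cat(self.df["drug_id"], sep="\x1f")

    def subset(self, mask_or_index) -> "ResponseDataset":
        """Dataset restricted to the given boolean mask or positional index."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = idx.nonzero()[0]
        sub = self.df.iloc[idx]
        return ResponseDataset(sub.reset_index(drop=True), measure=self.measure, name=self.name)

    def to_csv(self, path: str | Path) -> None:
        cols = ["cell_line_id", "drug_id", "tissue", self.measure]
        if "quality_p" in self.df.columns:
            cols.append("quality_p")
        self.df[cols].to_csv(path, index=False)


def load_response_table(path: str | Path, measure: str = "LN_IC50", name: str | None = None) -> ResponseDataset:
    """Load a long-format response CSV into a :class:`ResponseDataset`.

    Rows with a missing or non-finite response value are dropped; their count
    is available as ``dataset.n_dropped``.  Replicate rows (same cell line and
    drug) are all retained.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        raise SchemaError(f"empty response file: {path}")
    for col in ("cell_line_id", "drug_id", measure):
        if col not in df.columns:
            raise SchemaError(f"response table {path} missing required column {col!r}")
    if df.empty:
        raise SchemaError(f"response file has a header but no records: {path}")
    return ResponseDataset(df, measure=measure, name=name or path.stem)


def filter_by_curve_quality(dataset: ResponseDataset, alpha: float | None) -> ResponseDataset:
    """Keep records whose curve-fit p-value ``quality_p`` is at most ``alpha``.

    ``alpha=None`` disables filtering and returns the dataset unchanged, which
    is the default benchmarking behaviour (no quality filter).
    """
    if alpha is None:
        return dataset
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if "quality_p" not in dataset.df.columns or dataset.df["quality_p"].isna().any():
        raise ValueError("quality filtering requested but quality_p is absent or incomplete")
    keep = dataset.df["quality_p"].astype(float) <= alpha
    return ResponseDataset(
        dataset.df.loc[keep].reset_index(drop=True), measure=dataset.measure, name=dataset.name
    )


@dataclass
class FeatureSet:
    """Entity-to-feature views for one modality.

    ``views`` maps entity id to either a 1-D numeric vector (tabular modality,
    all vectors sharing one dimension) or an undirected simple
    :class:`networkx.Graph` (graph modality).
    """

    modality: str
    entity_kind: str  # "cell_line" or "drug"
    views: Mapping[str, np.ndarray] | Mapping[str, nx.Graph]

    def __post_init__(self) -> None:
        if self.entity_kind not in ("cell_line", "drug"):
            raise ValueError(f"entity_kind must be 'cell_line' or 'drug', got {self.entity_kind!r}")
        if self.is_graph:
            for eid, g in self.views.items():
                if any(u == v for u, v in g.edges):
                    raise ValueError(f"graph for entity {eid!r} has a self-loop")
        else:
            dims = {len(np.asarray(v)) for v in self.views.values()}
            if len(dims) > 1:
                raise ValueError(f"inconsistent feature dimensions in modality {self.modality!r}: {sorted(dims)}")

    @property
    def is_graph(self) -> bool:
        return any(isinstance(v, nx.Graph) for v in self.views.values())

    @property
    def dim(self) -> int | None:
        if self.is_graph or not self.views:
            return None
        return len(next(iter(self.views.values())))

    @property
    def entities(self) -> list[str]:
        return list(self.views.keys())

    def matrix(self, entity_ids) -> np.ndarray:
        """Stack feature vectors for the given ids into an (n, dim) array."""
        return np.vstack([np.asarray(self.views[e], dtype=float) for e in entity_ids])

    def to_csv(self, path: str | Path) -> None:
        if self.is_graph:
            raise ValueError("graph modalities are written as edge lists, not matrices")
        dim = self.dim or 0
        header = ["entity_id"] + [f"f{i + 1}" for i in range(dim)]
        rows = [[eid, *np.asarray(vec, dtype=float)] for eid, vec in self.views.items()]
        pd.DataFrame(rows, columns=header).to_csv(path, index=False)


def load_feature_matrix(path: str | Path, modality: str, entity_kind: str) -> FeatureSet:
    """Load a tabular feature CSV (first column entity id, rest numeric)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"feature table {path} needs an id column plus at least one feature")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique()
        raise SchemaError(f"duplicate entity id(s) in {path}: {', '.join(dupes)}")
    try:
        mat = df.iloc[:, 1:].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric feature value in {path}: {exc}") from exc
    if mat.isna().any().any():
        raise SchemaError(f"missing feature values in {path}")
    views = {eid: row for eid, row in zip(ids, mat.to_numpy())}
    return FeatureSet(modality=modality, entity_kind=entity_kind, views=views)


def load_edge_list(path: str | Path, modality: str, entity_kind: str = "drug") -> FeatureSet:
    """Load a graph modality from an edge-list CSV.

    Two schemas are accepted: ``entity_id,node_u,node_v`` (one graph per
    entity) or ``node_u,node_v`` (a single shared graph stored under the
    entity id ``"__shared__"``).
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[:3] == ["entity_id", "node_u", "node_v"]:
        views: dict[str, nx.Graph] = {}
        for eid, grp in df.groupby("entity_id", sort=False):
            g = nx.Graph()
            g.add_edges_from(zip(grp["node_u"].astype(str), grp["node_v"].astype(str)))
            views[str(eid)] = g
    elif cols[:2] == ["node_u", "node_v"]:
        g = nx.Graph()
        g.add_edges_from(zip(df["node_u"].astype(str), df["node_v"].astype(str)))
        views = {"__shared__": g}
    else:
        raise SchemaError(
            f"edge list {path} must have columns (entity_id,node_u,node_v) or (node_u,node_v), got {cols}"
        )
    return FeatureSet(modality=modality, entity_kind=entity_kind, views=views)
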