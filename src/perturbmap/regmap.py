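"""The perturbation effect map: modules, programmes, strengths, hubs.

The substrate is the gene × perturbation matrix of log2 fold-changes versus
NTC (one column per perturbation that passed the minimum-cells filter).
Co-regulated gene programmes are found by Pearson-correlation hierarchical
clustering of the rows; co-functional TF modules by Spearman-correlation
hierarchical clustering of the columns (average linkage in both).
Module→programme strength averages, over a module's perturbations, the mean
log2 fold-change of a programme's genes. Directed signed TF→TF edges follow
the knockout convention (loss of A depleting B means A activates B), module
connectivity is edge density between module pairs, and hubs are the module
members whose perturbation alters the most genes past the |log2FC|
threshold.

:class:`PerturbationMap` wraps the whole stage as a fit-style model whose
:meth:`~PerturbationMap.fit` returns a :class:`PerturbationMapResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_score

from .de import DifferentialTable

__all__ = [
    "EffectMatrix",
    "Partition",
    "TFNetwork",
    "build_gene_panel",
    "build_effect_matrix",
    "cluster_gene_programmes",
    "cluster_tf_modules",
    "select_n_clusters",
    "module_programme_strength",
    "tf_network_edges",
    "module_connectivity",
    "identify_hubs",
    "PerturbationMap",
    "PerturbationMapResults",
]


@dataclass
class EffectMatrix:
    """Panel genes × retained perturbations, log2 fold-changes vs NTC."""

    values: pd.DataFrame  # index: genes; columns: perturbations

    def __post_init__(self) -> None:
        if "NTC" in self.values.columns:
            raise ValueError("the effect matrix must not contain an NTC column")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("effect matrix entries must be finite")

    @property
    def gene_panel(self) -> list[str]:
        return list(self.values.index)

    @property
    def perturbations(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class Partition:
    """Cluster labels over one axis, with the linkage and metric recorded."""

    labels: pd.Series  # item -> cluster id (1..K)
    linkage: np.ndarray
    metric: str  # "pearson" or "spearman"

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())

    def members(self) -> dict[int, list[str]]:
        return {
            int(k): list(idx) for k, idx in self.labels.groupby(self.labels).groups.items()
        }


@dataclass
class TFNetwork:
    """Directed signed TF→TF regulatory edges under the knockout convention."""

    edges: pd.DataFrame  # columns: source, target, sign, magnitude
    lfc_threshold: float

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, sign=row.sign, magnitude=row.magnitude)
        return g


def build_gene_panel(
    cluster_marker_tables: Mapping[str, DifferentialTable],
    top_k: int = 100,
) -> list[str]:
    """Union of each cluster's top genes by log2 fold-change, deduplicated.

    Per table, genes are ranked by descending log2_fc (ties by ascending
    p-value, then lexicographic); the union keeps first-seen order over
    clusters sorted by name, so the panel is deterministic.
    """
    if not cluster_marker_tables:
        raise ValueError("at least one marker table is required")
    panel: dict[str, None] = {}
    for name in sorted(cluster_marker_tables):
        table = cluster_marker_tables[name].table
        if len(table) < top_k:
            warnings.warn(
                f"cluster {name!r} has only {len(table)} genes; taking all"
            )
        ordered = table.reset_index().sort_values(
            by=["log2_fc", "p_value", "feature_id"], ascending=[False, True, True]
        )
        for gene in ordered["feature_id"].head(top_k):
            panel.setdefault(gene, None)
    return list(panel)


def build_effect_matrix(
    de_tables: Mapping[str, DifferentialTable],
    panel: Sequence[str],
) -> EffectMatrix:
    """Assemble the panel × perturbation log2FC matrix from DE tables.

    Excluded perturbations are skipped; genes a table does not cover are
    filled with 0 (warned).
    """
    if not panel:
        raise ValueError("empty gene panel")
    cols = {}
    for target in de_tables:
        dt = de_tables[target]
        if dt.excluded:
            continue
        lfc = dt.table["log2_fc"].reindex(panel)
        n_missing = int(lfc.isna().sum())
        if n_missing:
            warnings.warn(
                f"perturbation {target!r}: {n_missing} panel genes missing; filled 0"
            )
        cols[target] = lfc.fillna(0.0)
    values = pd.DataFrame(cols, index=pd.Index(panel, name="gene"))
    return EffectMatrix(values=values)


def _correlation_distance(data: np.ndarray, metric: str) -> np.ndarray:
    """Condensed distance 1 − corr between rows of ``data``.

    Zero-variance rows have undefined correlation; the zero-correlation
    convention assigns them distance 1 to everything (warned).
    """
    if metric == "spearman":
        data = np.apply_along_axis(rankdata, 1, data)
    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant row(s): zero-correlation convention applied"
        )
    centered = data - data.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * data.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = centered @ centered.T / denom
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    return squareform(dist, checks=False)


def _cluster_axis(
    data: pd.DataFrame, n_clusters: int, metric: str
) -> Partition:
    if len(data) < n_clusters:
        raise ValueError(
            f"cannot cut {len(data)} items into {n_clusters} clusters"
        )
    condensed = _correlation_distance(data.to_numpy(dtype=float), metric)
    linkage = average(condensed)
    labels = fcluster(linkage, t=n_clusters, criterion="maxclust")
    return Partition(
        labels=pd.Series(labels, index=data.index, name="cluster"),
        linkage=linkage,
        metric=metric,
    )


def cluster_gene_programmes(E: EffectMatrix, n_programmes: int) -> Partition:
    """Pearson-correlation hierarchical clustering of the gene rows."""
    return _cluster_axis(E.values, n_programmes, "pearson")


def cluster_tf_modules(E: EffectMatrix, n_modules: int) -> Partition:
    """Spearman-correlation hierarchical clustering of the perturbation columns."""
    return _cluster_axis(E.values.T, n_modules, "spearman")


def select_n_clusters(
    E: EffectMatrix,
    axis: str,
    k_range: Sequence[int] = range(2, 13),
) -> int:
    """Pick the cut with the highest silhouette over a configured K range.

    ``axis`` is "genes" (Pearson, programmes) or "perturbations" (Spearman,
    modules). Silhouettes are computed on the same correlation distances the
    clustering uses.
    """
    if axis == "genes":
        data, metric = E.values, "pearson"
    elif axis == "perturbations":
        data, metric = E.values.T, "spearman"
    else:
        raise ValueError("axis must be 'genes' or 'perturbations'")
    condensed = _correlation_distance(data.to_numpy(dtype=float), metric)
    square = squareform(condensed)
    linkage = average(condensed)
    best_k, best_score = None, -np.inf
    for k in k_range:
        if k >= len(data):
            continue
        labels = fcluster(linkage, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(square, labels, metric="precomputed")
        if score > best_score:
            best_k, best_score = k, score
    if best_k is None:
        raise ValueError("no valid cut in the requested range")
    return int(best_k)


def module_programme_strength(
    E: EffectMatrix,
    modules: Partition,
    programmes: Partition,
) -> pd.DataFrame:
    """strength[k, q] = mean over perturbations in k of (mean over genes in q
    of E[g, p]) — the average downstream alteration of programme q induced
    by module k's perturbations."""
    mod_members = modules.members()
    prog_members = programmes.members()
    out = pd.DataFrame(
        index=pd.Index(sorted(mod_members), name="module"),
        columns=pd.Index(sorted(prog_members), name="programme"),
        dtype=float,
    )
    for k, perts in mod_members.items():
        for q, genes in prog_members.items():
            if not perts or not genes:
                warnings.warn(f"empty module {k} or programme {q}; NA strength")
                out.loc[k, q] = np.nan
                continue
            out.loc[k, q] = float(
                E.values.loc[genes, perts].mean(axis=0).mean()
            )
    return out


def tf_network_edges(
    de_tables: Mapping[str, DifferentialTable],
    tf_list: Sequence[str],
    lfc_threshold: float = 0.5,
) -> TFNetwork:
    """Directed signed edges source→target from each source's DE table.

    An edge exists when |log2_fc| of the target TF's gene in the source's
    table exceeds the threshold. Under knockout, depletion of the target
    upon loss of the source indicates positive regulation, so the edge sign
    is −sign(log2_fc); magnitude is |log2_fc|. Self-edges are excluded.
    """
    rows = []
    for source in tf_list:
        dt = de_tables.get(source)
        if dt is None or dt.excluded:
            continue
        lfcs = dt.table["log2_fc"]
        for target in tf_list:
            if target == source or target not in lfcs.index:
                continue
            lfc = float(lfcs[target])
            if abs(lfc) > lfc_threshold:
                rows.append(
                    (source, target, "+" if lfc < 0 else "-", abs(lfc))
                )
    edges = pd.DataFrame(rows, columns=["source", "target", "sign", "magnitude"])
    return TFNetwork(edges=edges, lfc_threshold=lfc_threshold)


def module_connectivity(
    network: TFNetwork,
    modules: Partition,
    normalization: str = "product",
    signed: bool = False,
) -> pd.DataFrame:
    """K × K inter-module edge density.

    conn[i, j] counts directed edges from module i members to module j
    members, normalized by |i|·|j| ordered pairs (|i|·(|i|−1) on the
    diagonal). ``normalization="sum"`` divides by |i|+|j| instead. With
    ``signed=True`` each edge contributes ±1 by its sign before
    normalization.
    """
    members = modules.members()
    module_of = {t: k for k, ts in members.items() for t in ts}
    uncovered = (set(network.edges["source"]) | set(network.edges["target"])) - set(
        module_of
    )
    if uncovered:
        raise ValueError(f"network nodes outside the partition: {sorted(uncovered)[:5]}")
    keys = sorted(members)
    out = pd.DataFrame(0.0, index=keys, columns=keys)
    counts = pd.DataFrame(0.0, index=keys, columns=keys)
    for row in network.edges.itertuples(index=False):
        w = (1.0 if row.sign == "+" else -1.0) if signed else 1.0
        counts.loc[module_of[row.source], module_of[row.target]] += w
    for i in keys:
        for j in keys:
            ni, nj = len(members[i]), len(members[j])
            if normalization == "product":
                denom = ni * (ni - 1) if i == j else ni * nj
            elif normalization == "sum":
                denom = ni + nj
            else:
                raise ValueError(f"unknown normalization {normalization!r}")
            out.loc[i, j] = counts.loc[i, j] / denom if denom > 0 else np.nan
    return out


def identify_hubs(
    de_tables: Mapping[str, DifferentialTable],
    modules: Partition,
    lfc_threshold: float = 0.5,
    top_n: int = 1,
) -> pd.DataFrame:
    """Per module, rank TFs by how many genes their perturbation alters.

    The count is of genes with |log2_fc| > threshold in the TF's DE table.
    Ties break by total |log2_fc| (descending), then lexicographic. Returns
    the top_n per module with their counts.
    """
    rows = []
    for k, perts in modules.members().items():
        scored = []
        for tf in perts:
            dt = de_tables.get(tf)
            if dt is None or dt.excluded:
                count, weight = 0, 0.0
            else:
                mask = dt.table["log2_fc"].abs() > lfc_threshold
                count = int(mask.sum())
                weight = float(dt.table["log2_fc"].abs().sum())
            scored.append((tf, count, weight))
        scored.sort(key=lambda t: (-t[1], -t[2], t[0]))
        for rank, (tf, count, weight) in enumerate(scored[:top_n], start=1):
            rows.append((k, rank, tf, count))
    return pd.DataFrame(rows, columns=["module", "rank", "tf", "n_de_genes"])


# ---------------------------------------------------------------------------
# Model-style front end


class PerturbationMap:
    """Dual-clustering model of a perturbation effect matrix.

    Parameters
    ----------
    effect_matrix
        Panel genes × retained perturbations log2FC matrix.
    de_tables
        The per-perturbation DE tables behind the matrix (needed for the
        network, connectivity and hub stages; optional otherwise).
    """

    def __init__(
        self,
        effect_matrix: EffectMatrix,
        de_tables: Mapping[str, DifferentialTable] | None = None,
    ) -> None:
        self.effect_matrix = effect_matrix
        self.de_tables = dict(de_tables or {})

    @classmethod
    def from_de_tables(
        cls, de_tables: Mapping[str, DifferentialTable], panel: Sequence[str]
    ) -> "PerturbationMap":
        return cls(build_effect_matrix(de_tables, panel), de_tables)

    def fit(
        self,
        n_modules: int | None = None,
        n_programmes: int | None = None,
        lfc_threshold: float = 0.5,
        hub_top_n: int = 1,
        k_range: Sequence[int] = range(2, 13),
    ) -> "PerturbationMapResults":
        """Cluster both axes and derive strengths, network, hubs.

        With ``n_modules`` or ``n_programmes`` left as None, the cut is
        chosen automatically at the highest-silhouette K in ``k_range``.
        """
        E = self.effect_matrix
        if n_programmes is None:
            n_programmes = select_n_clusters(E, "genes", k_range)
        if n_modules is None:
            n_modules = select_n_clusters(E, "perturbations", k_range)
        programmes = cluster_gene_programmes(E, n_programmes)
        modules = cluster_tf_modules(E, n_modules)
        strength = module_programme_strength(E, modules, programmes)
        network = None
        connectivity = None
        hubs = None
        if self.de_tables:
            network = tf_network_edges(
                self.de_tables, E.perturbations, lfc_threshold
            )
            connectivity = module_connectivity(network, modules)
            hubs = identify_hubs(self.de_tables, modules, lfc_threshold, hub_top_n)
        return PerturbationMapResults(
            model=self,
            modules=modules,
            programmes=programmes,
            strength=strength,
            network=network,
            connectivity=connectivity,
            hubs=hubs,
        )


@dataclass
class PerturbationMapResults:
    model: PerturbationMap
    modules: Partition
    programmes: Partition
    strength: pd.DataFrame
    network: TFNetwork | None = None
    connectivity: pd.DataFrame | None = None
    hubs: pd.DataFrame | None = None

    def plot_strength(self, ax=None):
        from .plotting import plot_strength_heatmap

        return plot_strength_heatmap(self, ax=ax)

    def summary(self) -> str:
        E = self.model.effect_matrix
        lines = [
            "Perturbation effect map",
            "=" * 45,
            f"genes × perturbations: {len(E.gene_panel)} × {len(E.perturbations)}",
            f"TF modules (Spearman):   {self.modules.n_clusters}",
            f"gene programmes (Pearson): {self.programmes.n_clusters}",
            "",
            "module → programme strength (mean log2FC):",
            self.strength.round(3).to_string(),
        ]
        if self.network is not None:
            lines += ["", f"TF edges (|log2FC| > {self.network.lfc_threshold}): "
                      f"{len(self.network.edges)}"]
        if self.hubs is not None and len(self.hubs):
            hub_str = ", ".join(
                f"M{row.module}:{row.tf}({row.n_de_genes})"
                for row in self.hubs[self.hubs["rank"] == 1].itertuples(index=False)
            )
            lines.append(f"hub TFs: {hub_str}")
        return "\n".join(lines)
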