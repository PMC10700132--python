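"""Differential expression, signature scoring, state gating, set enrichment.

Per-perturbation DE compares each perturbation's singlets against NTC
singlets gene-by-gene with the two-sided Wilcoxon rank-sum test; log2
fold-changes are computed on de-logged mean expression. Perturbations with
fewer than 48 cells are excluded (flagged, not dropped silently). Cluster
markers are the one-vs-rest variant of the same computation. Signature
scores use expression-matched binned control genes; cell states are gated
on Tox / Tcf7 / Havcr2 / Mki67.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import GuideAssignment
from .core_stats import NormalizedMatrix, bh_adjust, fisher_exact, rank_sum_test
from .manifest import NTC

__all__ = [
    "DifferentialTable",
    "SignatureScore",
    "StateLabeling",
    "MarkerConfig",
    "perturbation_de",
    "cluster_markers",
    "signature_score",
    "gate_states",
    "geneset_fisher",
    "read_gmt",
]

LFC_EPS = 1e-9


@dataclass
class DifferentialTable:
    """Rows of (feature_id, log2_fc, p_value, fdr, n_group1, n_group2)."""

    table: pd.DataFrame
    group1: str
    group2: str = NTC
    excluded: bool = False
    exclusion_reason: str = ""

    def significant(self, lfc_threshold: float = 0.5, fdr_threshold: float = 0.05) -> pd.DataFrame:
        t = self.table
        return t[(t["log2_fc"].abs() > lfc_threshold) & (t["fdr"] < fdr_threshold)]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class SignatureScore:
    scores: pd.Series  # per cell
    signature_name: str
    n_bins: int
    n_ctrl: int
    seed: int


@dataclass
class MarkerConfig:
    """Gate genes and thresholds for state labelling.

    Thresholds of None default to the per-gene median of normalized
    expression over all cells (upper-median split).
    """

    tox: str = "Tox"
    tcf7: str = "Tcf7"
    havcr2: str = "Havcr2"
    mki67: str = "Mki67"
    tox_threshold: float | None = None
    tcf7_threshold: float | None = None
    havcr2_threshold: float | None = None
    mki67_threshold: float | None = None


@dataclass
class StateLabeling:
    labels: pd.Series  # per cell: Tpex1/Tpex2/Tex1/Tex2/excluded
    config: MarkerConfig
    thresholds: dict[str, float] = field(default_factory=dict)


def _de_between(
    norm: NormalizedMatrix,
    cells1: Sequence[str],
    cells2: Sequence[str],
    name1: str,
    name2: str,
) -> DifferentialTable:
    index = {c: i for i, c in enumerate(norm.cell_ids)}
    rows1 = [index[c] for c in cells1]
    rows2 = [index[c] for c in cells2]
    x = norm.values[rows1]
    y = norm.values[rows2]
    mean1 = np.expm1(x).mean(axis=0)
    mean2 = np.expm1(y).mean(axis=0)
    lfc = np.log2((mean1 + LFC_EPS) / (mean2 + LFC_EPS))
    pvals = np.empty(len(norm.gene_ids))
    for j in range(len(norm.gene_ids)):
        pvals[j] = rank_sum_test(x[:, j], y[:, j]).p_value
    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "n_group1": len(rows1),
            "n_group2": len(rows2),
        },
        index=pd.Index(norm.gene_ids, name="feature_id"),
    )
    return DifferentialTable(table=table, group1=name1, group2=name2)


def perturbation_de(
    norm: NormalizedMatrix,
    assignment: GuideAssignment,
    target: str,
    min_cells: int = 48,
) -> DifferentialTable:
    """DE of one perturbation's singlets against NTC singlets.

    log2_fc compares de-logged mean expression with a small ε guard; p is
    the two-sided rank-sum test; fdr is BH across the table's genes.
    Targets with fewer than ``min_cells`` singlets return an empty table
    with ``excluded=True`` and the reason recorded.
    """
    have = set(norm.cell_ids)
    cells_t = [c for c in assignment.singlet_cells(target) if c in have]
    cells_ntc = [c for c in assignment.singlet_cells(NTC) if c in have]
    if not cells_ntc:
        raise ValueError("no NTC singlets in the normalized matrix")
    if len(cells_t) < min_cells:
        return DifferentialTable(
            table=pd.DataFrame(
                columns=["log2_fc", "p_value", "fdr", "n_group1", "n_group2"],
                index=pd.Index([], name="feature_id"),
            ),
            group1=target,
            excluded=True,
            exclusion_reason=f"{len(cells_t)} singlets < min_cells={min_cells}",
        )
    return _de_between(norm, cells_t, cells_ntc, target, NTC)


def cluster_markers(
    norm: NormalizedMatrix, cluster_labels: pd.Series
) -> dict[str, DifferentialTable]:
    """One-vs-rest DE per cluster, same statistics as perturbation DE."""
    labels = cluster_labels.loc[[c for c in norm.cell_ids if c in cluster_labels.index]]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("cluster_markers requires at least 2 clusters")
    out: dict[str, DifferentialTable] = {}
    for cl in clusters:
        cells_in = list(labels.index[labels == cl])
        cells_out = list(labels.index[labels != cl])
        if len(cells_in) == 1:
            warnings.warn(f"cluster {cl!r} is a singleton; p-values are approximate")
        out[str(cl)] = _de_between(norm, cells_in, cells_out, str(cl), "rest")
    return out


def signature_score(
    norm: NormalizedMatrix,
    gene_set: Sequence[str],
    signature_name: str = "signature",
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> SignatureScore:
    """Binned-control signature score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of mean
    expression; for each signature gene, ``n_ctrl`` control genes are drawn
    (with replacement) from its bin. The score is mean(signature) −
    mean(controls) per cell, so it is centred at 0 for a signature that
    behaves like expression-matched background.
    """
    present = [g for g in gene_set if g in norm.gene_ids]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    rng = np.random.default_rng(seed)
    avg = norm.values.mean(axis=0)
    order = pd.Series(avg, index=norm.gene_ids)
    n_bins_eff = min(n_bins, len(order))
    # equal-frequency binning on mean expression, ties broken by rank
    ranks = order.rank(method="first")
    bins = pd.Series(
        np.ceil(ranks / len(order) * n_bins_eff).astype(int) - 1,
        index=order.index,
    )
    by_bin = {b: list(idx) for b, idx in bins.groupby(bins).groups.items()}
    gene_col = {g: j for j, g in enumerate(norm.gene_ids)}
    sig_cols = [gene_col[g] for g in present]
    ctrl_cols: list[int] = []
    for g in present:
        pool = by_bin[bins[g]]
        draws = rng.choice(len(pool), size=n_ctrl, replace=True)
        ctrl_cols.extend(gene_col[pool[d]] for d in draws)
    scores = norm.values[:, sig_cols].mean(axis=1) - norm.values[:, ctrl_cols].mean(axis=1)
    return SignatureScore(
        scores=pd.Series(scores, index=norm.cell_ids, name=signature_name),
        signature_name=signature_name,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
    )


def gate_states(
    norm: NormalizedMatrix, marker_config: MarkerConfig | None = None
) -> StateLabeling:
    """Deterministic marker-gating surrogate for state annotation.

    Tox-negative cells are excluded. Among Tox-positive cells, the
    Tcf7-vs-Havcr2 margin decides precursor (Tpex) vs terminal (Tex)
    exhaustion, and Mki67 splits each into a quiescent and a proliferative
    state: Tpex1 (Mki67 low), Tpex2 (high), Tex1 (high), Tex2 (low).
    Thresholds default to per-gene medians of normalized expression.
    """
    cfg = marker_config or MarkerConfig()
    values = {}
    for attr in ("tox", "tcf7", "havcr2", "mki67"):
        gene = getattr(cfg, attr)
        try:
            col = norm.gene_index(gene)
        except KeyError:
            raise ValueError(f"gate gene {gene!r} missing from the matrix") from None
        values[attr] = norm.values[:, col]
    thresholds = {}
    for attr in ("tox", "tcf7", "havcr2", "mki67"):
        configured = getattr(cfg, f"{attr}_threshold")
        thresholds[attr] = (
            float(np.median(values[attr])) if configured is None else float(configured)
        )
    tox_pos = values["tox"] > thresholds["tox"]
    pex_margin = (values["tcf7"] - thresholds["tcf7"]) - (
        values["havcr2"] - thresholds["havcr2"]
    )
    proliferative = values["mki67"] > thresholds["mki67"]
    labels = np.where(
        ~tox_pos,
        "excluded",
        np.where(
            pex_margin > 0,
            np.where(proliferative, "Tpex2", "Tpex1"),
            np.where(proliferative, "Tex1", "Tex2"),
        ),
    )
    return StateLabeling(
        labels=pd.Series(labels, index=norm.cell_ids, name="state"),
        config=cfg,
        thresholds=thresholds,
    )


def geneset_fisher(
    de_features: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Fisher's exact enrichment of DE features in each gene set.

    For every set: [[in-set ∧ DE, in-set ∧ ¬DE], [¬set ∧ DE, ¬set ∧ ¬DE]]
    through the exact test; BH adjustment across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    de = set(de_features) & uni
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & uni
        a = len(s & de)
        b = len(s - de)
        c = len(de - s)
        d = len(uni) - a - b - c
        odds, p = fisher_exact([[a, b], [c, d]])
        rows.append((name, a, len(s), odds, p))
    out = pd.DataFrame(
        rows, columns=["gene_set", "n_overlap", "n_set", "odds_ratio", "p_value"]
    ).set_index("gene_set")
    out["fdr"] = bh_adjust(out["p_value"])
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
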