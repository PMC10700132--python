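"""Bulk dual-guide genetic-interaction screen statistics.

Counts of sgRNA reads across screen samples (input, spleen, tumour, Tpex,
Tex compartments in a control arm and a perturbed arm) are median-of-ratios
normalized, converted to NTC-referenced gene-level log2 fold-changes, and
candidate modifier genes are nominated from FC/FC comparisons between arms:
a gene rescues the perturbed phenotype when it is strongly depleted in the
perturbed arm while remaining near-neutral in the control arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .manifest import NTC, LibraryManifest

__all__ = [
    "ScreenCounts",
    "GeneLFCTable",
    "median_normalize",
    "sgrna_lfc",
    "gene_lfc",
    "fcfc_nominate",
    "intersect_parameters",
]

Rule = Literal["strict_order", "window"]


@dataclass
class ScreenCounts:
    """sgRNA × sample integer counts with per-sample arm/compartment labels."""

    counts: pd.DataFrame  # index: sgRNA ids; columns: sample names
    sample_meta: pd.DataFrame  # index: sample names; columns: arm, compartment
    guide_targets: pd.Series  # index: sgRNA ids; value: gene symbol or NTC

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.sample_meta.index):
            self.sample_meta = self.sample_meta.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("screen counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("screen counts must be integral")
        missing = set(self.counts.index) - set(self.guide_targets.index)
        if missing:
            raise ValueError(f"sgRNAs without a manifest target: {sorted(missing)[:5]}")

    @property
    def ntc_guides(self) -> list[str]:
        return [g for g in self.counts.index if self.guide_targets[g] == NTC]


@dataclass
class GeneLFCTable:
    """Per-gene log2 fold-changes for one sample comparison."""

    table: pd.DataFrame  # index: gene; columns: lfc, n_sgRNAs
    comparison: tuple[str, str]
    ntc_centered: bool


def median_normalize(
    counts: ScreenCounts, method: Literal["median_ratio", "median_count"] = "median_ratio"
) -> pd.DataFrame:
    """Normalize read counts across samples for sequencing depth.

    ``median_ratio`` (default): each sample is scaled by the median, over
    sgRNAs, of its ratio to the per-sgRNA geometric-mean pseudo-reference,
    excluding sgRNAs with a zero count in any sample from the median. This is
    the median-of-ratios estimator standard in count-based screens.
    ``median_count`` scales each sample by its own median count instead.
    """
    df = counts.counts.astype(float)
    if df.shape[1] < 2:
        raise ValueError("median normalization requires at least 2 samples")
    if (df.sum(axis=0) == 0).any():
        raise ValueError("a sample has all-zero counts")
    if method == "median_count":
        med = df.median(axis=0)
        if (med == 0).any():
            raise ValueError("a sample has median count zero")
        factors = med / med.mean()
    elif method == "median_ratio":
        positive = (df > 0).all(axis=1)
        if not positive.any():
            raise ValueError("no sgRNA has positive counts in every sample")
        logref = np.log(df.loc[positive]).mean(axis=1)
        ratios = np.log(df.loc[positive]).sub(logref, axis=0)
        factors = np.exp(ratios.median(axis=0))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return df.div(factors, axis=1)


def sgrna_lfc(
    norm_counts: pd.DataFrame,
    sample_a: str,
    sample_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sgRNA log2((a + c)/(b + c)) between two normalized samples."""
    for s in (sample_a, sample_b):
        if s not in norm_counts.columns:
            raise KeyError(f"sample {s!r} not present")
    a = norm_counts[sample_a] + pseudocount
    b = norm_counts[sample_b] + pseudocount
    out = np.log2(a / b)
    out.name = f"{sample_a}_vs_{sample_b}"
    return out


def gene_lfc(
    sgrna_lfcs: pd.Series,
    guide_targets: pd.Series,
    center: Literal["median", "mean", "none"] = "median",
) -> GeneLFCTable:
    """Aggregate sgRNA log2 fold-changes to gene level, NTC-referenced.

    The gene value is the mean of its sgRNAs' lfcs; all values are then
    centered by subtracting the median (default) of the NTC sgRNA lfcs so
    that the non-targeting null sits at zero.
    """
    targets = guide_targets.loc[sgrna_lfcs.index]
    grouped = sgrna_lfcs.groupby(targets)
    table = pd.DataFrame({"lfc": grouped.mean(), "n_sgRNAs": grouped.size()})
    ntc_vals = sgrna_lfcs[targets == NTC]
    centered = False
    if center != "none":
        if ntc_vals.empty:
            warnings.warn("no NTC sgRNAs found; centering skipped")
        else:
            shift = ntc_vals.median() if center == "median" else ntc_vals.mean()
            table["lfc"] = table["lfc"] - shift
            centered = True
    name = sgrna_lfcs.name or "a_vs_b"
    parts = tuple(name.split("_vs_")) if "_vs_" in str(name) else (str(name), "")
    return GeneLFCTable(table=table, comparison=parts, ntc_centered=centered)


def fcfc_nominate(
    gene_lfc_perturbed: pd.Series,
    gene_lfc_control: pd.Series,
    rule: Rule = "strict_order",
    t_rescue: float = -1.0,
    t_window: float = 1.0,
) -> set[str]:
    """Select candidate modifier genes from an FC/FC comparison of two arms.

    ``strict_order``: lfc_perturbed < t_rescue and
    lfc_perturbed < lfc_control < t_window (depletion specific to, and
    strongest in, the perturbed arm).
    ``window``: lfc_perturbed < t_rescue and t_rescue < lfc_control <
    t_window (near-neutral control arm).
    """
    genes = gene_lfc_perturbed.index.intersection(gene_lfc_control.index)
    if len(genes) < len(gene_lfc_perturbed) or len(genes) < len(gene_lfc_control):
        warnings.warn("arms cover different gene sets; using the intersection")
    p = gene_lfc_perturbed.loc[genes]
    c = gene_lfc_control.loc[genes]
    if rule == "strict_order":
        mask = (p < t_rescue) & (p < c) & (c < t_window)
    elif rule == "window":
        mask = (p < t_rescue) & (t_rescue < c) & (c < t_window)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return {g for g in genes[mask] if g != NTC}


def intersect_parameters(
    candidate_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Intersect per-parameter candidate sets, keeping provenance.

    Returns a frame indexed by every gene appearing in any set, one boolean
    column per parameter, and ``final`` true only for genes in all sets.
    """
    if not candidate_sets:
        raise ValueError("at least one parameter set is required")
    all_genes = sorted(set().union(*candidate_sets.values()))
    out = pd.DataFrame(index=pd.Index(all_genes, name="gene"))
    for name, genes in candidate_sets.items():
        out[name] = [g in genes for g in all_genes]
    out["final"] = out.all(axis=1)
    return out
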