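"""Perturbation-level abundance statistics.

Enrichment or depletion of each gene-level perturbation is measured as the
log2 ratio of its per-sgRNA cell yield to the NTC per-sgRNA cell yield —
dividing each side by its sgRNA count accounts for the very different guide
numbers behind a gene (4) and the NTC pool (80). State-specific regulators
are scored by comparing a perturbation's sgRNA abundance inside one cell
state against the complement (or one other state, pairwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assignment import GuideAssignment
from .manifest import NTC

__all__ = [
    "AbundanceResult",
    "StateEnrichment",
    "abundance_lfc",
    "abundance_from_assignment",
    "state_enrichment",
    "pairwise_state_enrichment",
]


@dataclass
class AbundanceResult:
    """Per-target cell counts and log2 per-sgRNA yield ratio vs NTC."""

    table: pd.DataFrame  # index: target; columns: n_cells, n_sgRNAs, log2_ratio_vs_ntc
    pseudocount: float


@dataclass
class StateEnrichment:
    """Per-(target, state) log2 enrichment vs the complement states."""

    per_state: pd.DataFrame  # index: target; one column per state
    pseudocount: float


def abundance_lfc(
    cells_per_target: pd.Series | dict[str, int],
    sgrnas_per_target: pd.Series | dict[str, int],
    ntc_cells: int,
    ntc_sgrnas: int,
    pseudocount: float = 1.0,
) -> AbundanceResult:
    """log2 of per-sgRNA cell yield of each target relative to NTC.

    ratio(t) = ((n_t + c)/k_t) / ((n_NTC + c)/k_NTC) with pseudocount c on
    cell counts, so zero-cell targets still get a finite depletion score.
    """
    cells = pd.Series(cells_per_target, dtype=float)
    sgrnas = pd.Series(sgrnas_per_target, dtype=float)
    if ntc_cells <= 0:
        raise ValueError("ntc_cells must be positive")
    if ntc_sgrnas <= 0 or (sgrnas <= 0).any():
        raise ValueError("sgRNA counts must be positive")
    if pseudocount == 0 and ((cells == 0).any() or ntc_cells == 0):
        raise ValueError(
            "zero cell count with pseudocount 0; pass pseudocount > 0"
        )
    ntc_yield = (ntc_cells + pseudocount) / ntc_sgrnas
    ratio = np.log2(((cells + pseudocount) / sgrnas) / ntc_yield)
    table = pd.DataFrame(
        {
            "n_cells": cells.astype(int),
            "n_sgRNAs": sgrnas.astype(int),
            "log2_ratio_vs_ntc": ratio,
        }
    )
    table.index.name = "target"
    return AbundanceResult(table=table, pseudocount=pseudocount)


def abundance_from_assignment(
    assignment: GuideAssignment,
    sgrnas_per_gene: int = 4,
    ntc_sgrnas: int = 80,
    pseudocount: float = 1.0,
) -> AbundanceResult:
    """Convenience wrapper: singlet counts per target straight to ratios."""
    counts = assignment.cells_per_target()
    ntc_cells = int(counts.get(NTC, 0))
    gene_counts = counts.drop(NTC, errors="ignore")
    if ntc_cells == 0:
        raise ValueError("no NTC singlets; abundance reference undefined")
    return abundance_lfc(
        gene_counts,
        {t: sgrnas_per_gene for t in gene_counts.index},
        ntc_cells,
        ntc_sgrnas,
        pseudocount,
    )


def _freq_table(
    assignment: GuideAssignment, state_labels: pd.Series
) -> pd.DataFrame:
    """Targets × states singlet count table."""
    singlets = assignment.singlets()
    missing = set(singlets.index) - set(state_labels.index)
    if missing:
        raise ValueError(
            f"{len(missing)} singlet cells lack a state label (e.g. {sorted(missing)[:3]})"
        )
    df = pd.DataFrame(
        {
            "target": singlets["target"],
            "state": state_labels.loc[singlets.index],
        }
    )
    return df.groupby(["target", "state"]).size().unstack(fill_value=0)


def state_enrichment(
    assignment: GuideAssignment,
    state_labels: pd.Series,
    pseudocount: float = 1.0,
) -> StateEnrichment:
    """Per-(target, state) log2( freq(t|s) / freq(t|not s) ).

    Frequencies are computed within singlets of each compartment; the
    pseudocount is applied to counts on both sides. States with zero
    singlets give NA columns with a warning.
    """
    counts = _freq_table(assignment, state_labels)
    out = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    col_totals = counts.sum(axis=0)
    grand = counts.to_numpy().sum()
    for s in counts.columns:
        n_s = col_totals[s]
        n_rest = grand - n_s
        if n_s == 0 or n_rest == 0:
            warnings.warn(f"state {s!r} has no singlets on one side; NA reported")
            out[s] = np.nan
            continue
        in_s = counts[s].astype(float)
        in_rest = counts.drop(columns=s).sum(axis=1).astype(float)
        f_s = (in_s + pseudocount) / (n_s + pseudocount)
        f_rest = (in_rest + pseudocount) / (n_rest + pseudocount)
        out[s] = np.log2(f_s / f_rest)
    return StateEnrichment(per_state=out, pseudocount=pseudocount)


def pairwise_state_enrichment(
    assignment: GuideAssignment,
    state_labels: pd.Series,
    state_a: str,
    state_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2( freq(t|state_a) / freq(t|state_b) ) per target.

    Antisymmetric in (state_a, state_b) by construction.
    """
    counts = _freq_table(assignment, state_labels)
    for s in (state_a, state_b):
        if s not in counts.columns or counts[s].sum() == 0:
            raise ValueError(f"state {s!r} has no singlets")
    f_a = (counts[state_a] + pseudocount) / (counts[state_a].sum() + pseudocount)
    f_b = (counts[state_b] + pseudocount) / (counts[state_b].sum() + pseudocount)
    out = np.log2(f_a / f_b)
    out.name = f"{state_a}_vs_{state_b}"
    return out
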