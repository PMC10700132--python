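"""Per-cell guide calling, singlet classification, and expression QC.

A droplet is usable when it passes expression QC (mitochondrial fraction,
feature and UMI ceilings) and carries more than one sgRNA UMI in total.
Detected guides are reduced to a gene-level call: cells whose guides all
target one gene (or are all non-targeting) are singlets — the unit of every
downstream analysis; cells with guides against two or more genes are
discarded as multi-gene.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_stats import CountMatrix
from .manifest import LibraryManifest

__all__ = [
    "GuideAssignment",
    "QCReport",
    "qc_filter",
    "call_guides",
    "assign_cells",
    "capture_stats",
]


@dataclass
class QCReport:
    n_input: int = 0
    n_pass_expression_qc: int = 0
    n_with_sgRNA: int = 0
    fraction_with_sgRNA: float | None = None
    fraction_same_vector_among_two_guide_cells: float | None = None
    removed_by_filter: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class GuideAssignment:
    """Gene-level perturbation call per cell.

    ``table`` is indexed by cell id with columns: status (singlet /
    multi_gene / unassigned), target (singlets only, else ""), construct_id
    (when both detected guides share one construct, else ""), guides
    (comma-joined detected guide ids), umis (comma-joined matching counts).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        statuses = set(self.table["status"])
        bad = statuses - {"singlet", "multi_gene", "unassigned"}
        if bad:
            raise ValueError(f"unknown assignment status values: {bad}")

    def singlets(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "singlet"]

    def singlet_cells(self, target: str | None = None) -> list[str]:
        s = self.singlets()
        if target is not None:
            s = s[s["target"] == target]
        return list(s.index)

    def cells_per_target(self) -> pd.Series:
        return self.singlets().groupby("target").size().sort_values(ascending=False)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="cell_id")


def qc_filter(
    expression: CountMatrix,
    mito_prefix: str = "mt-",
    max_mito_fraction: float = 0.10,
    max_features: int = 6000,
    max_umis: int = 60000,
) -> tuple[list[str], QCReport]:
    """Expression-level cell QC with strict upper bounds.

    Keeps cells with mitochondrial read fraction < max_mito_fraction,
    detected features < max_features and total UMIs < max_umis. Removal
    counts are recorded per filter (a cell failing several filters counts
    once per filter it fails).
    """
    dense = expression.to_dense()
    totals = dense.sum(axis=1)
    n_features = (dense > 0).sum(axis=1)
    mito_mask = np.array([f.startswith(mito_prefix) for f in expression.feature_ids])
    report = QCReport(n_input=len(expression.cell_ids))
    if mito_mask.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(
                totals > 0, dense[:, mito_mask].sum(axis=1) / np.maximum(totals, 1), 0.0
            )
        pass_mito = mito_frac < max_mito_fraction
    else:
        warnings.warn(f"no features with prefix {mito_prefix!r}; mito filter skipped")
        pass_mito = np.ones(len(totals), dtype=bool)
    pass_feat = n_features < max_features
    pass_umi = totals < max_umis
    nonempty = totals > 0
    keep = pass_mito & pass_feat & pass_umi & nonempty
    report.removed_by_filter = {
        "mito_fraction": int((~pass_mito).sum()),
        "max_features": int((~pass_feat).sum()),
        "max_umis": int((~pass_umi).sum()),
        "zero_counts": int((~nonempty).sum()),
    }
    report.n_pass_expression_qc = int(keep.sum())
    kept = [c for c, k in zip(expression.cell_ids, keep) if k]
    return kept, report


def call_guides(
    sgrna_counts: CountMatrix,
    min_guide_umi: int = 2,
    min_total_umi: int = 2,
    dominance_fraction: float = 0.10,
) -> dict[str, dict[str, int]]:
    """Detect guides per cell from the sgRNA UMI matrix.

    Cells whose total sgRNA UMI count is below ``min_total_umi`` (default 2,
    i.e. droplets need more than one sgRNA UMI) get no detected guides. A
    guide is detected when its UMI count is at least ``min_guide_umi``, or
    when it has at least one UMI and at least ``dominance_fraction`` of the
    cell's top guide count — the dominance rule suppresses single-molecule
    ambient contamination next to a strongly captured guide. Set
    ``dominance_fraction=0`` to disable the rule (every ≥1-UMI guide is then
    kept when min_guide_umi ≤ 1).
    """
    if sgrna_counts.feature_kind != "sgRNA":
        raise ValueError("call_guides expects an sgRNA-kind count matrix")
    dense = sgrna_counts.to_dense()
    guide_ids = np.array(sgrna_counts.feature_ids)
    detected: dict[str, dict[str, int]] = {}
    totals = dense.sum(axis=1)
    for i, cell in enumerate(sgrna_counts.cell_ids):
        if totals[i] < min_total_umi:
            detected[cell] = {}
            continue
        row = dense[i]
        top = row.max()
        keep = row >= min_guide_umi
        if dominance_fraction > 0 and top > 0:
            keep |= (row >= 1) & (row >= dominance_fraction * top)
        detected[cell] = {
            g: int(c) for g, c in zip(guide_ids[keep], row[keep])
        }
        if not detected[cell]:
            detected[cell] = {}
    return detected


def assign_cells(
    detected: Mapping[str, Mapping[str, int]],
    manifest: LibraryManifest,
) -> GuideAssignment:
    """Reduce detected guides to gene-level perturbation calls.

    Cells whose detected guides all target one gene (or NTC) are singlets;
    guides against two or more genes make the cell multi_gene (removed from
    downstream analyses); no detected guides leaves the cell unassigned.
    Two same-gene guides on different constructs still count as a singlet
    (gene-level analyses only need the target); the construct is resolved
    only when all detected guides share one.
    """
    lookup = manifest.guide_lookup()
    con_of = manifest.construct_of_guide()
    rows = []
    for cell, guides in detected.items():
        unknown = set(guides) - set(lookup)
        if unknown:
            raise ValueError(f"cell {cell}: guides not in manifest: {sorted(unknown)}")
        if not guides:
            rows.append((cell, "unassigned", "", "", "", ""))
            continue
        targets = {lookup[g].target for g in guides}
        gids = sorted(guides, key=lambda g: (-guides[g], g))
        gstr = ",".join(gids)
        ustr = ",".join(str(guides[g]) for g in gids)
        if len(targets) == 1:
            cons = {con_of[g] for g in guides}
            construct = cons.pop() if len(cons) == 1 else ""
            rows.append((cell, "singlet", targets.pop(), construct, gstr, ustr))
        else:
            rows.append((cell, "multi_gene", "", "", gstr, ustr))
    table = pd.DataFrame(
        rows, columns=["cell_id", "status", "target", "construct_id", "guides", "umis"]
    ).set_index("cell_id")
    return GuideAssignment(table)


def capture_stats(
    assignment: GuideAssignment, qc: QCReport | None = None
) -> QCReport:
    """Capture-quality summary: assigned fraction and same-vector fraction.

    The same-vector fraction is computed among cells with exactly two
    detected guides: the share whose two guides sit on the same construct.
    Reported as None when there are no two-guide cells.
    """
    report = qc if qc is not None else QCReport(n_input=len(assignment.table))
    tab = assignment.table
    with_sg = tab["status"] != "unassigned"
    report.n_with_sgRNA = int(with_sg.sum())
    denom = report.n_pass_expression_qc or len(tab)
    report.fraction_with_sgRNA = report.n_with_sgRNA / denom if denom else None

    two_guide = tab[
        tab["guides"].map(lambda s: isinstance(s, str) and s.count(",") == 1)
    ]
    if len(two_guide) == 0:
        report.fraction_same_vector_among_two_guide_cells = None
        return report
    same = 0
    for _, row in two_guide.iterrows():
        if row["status"] == "singlet" and row["construct_id"]:
            same += 1
    report.fraction_same_vector_among_two_guide_cells = same / len(two_guide)
    return report
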