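"""TF library design: 2-of-3 nomination, cross-dataset ranking, motif stats.

Candidate TFs are flagged per dataset on three evidence channels —
differential expression (DE), differential chromatin accessibility (DA) and
motif enrichment (ME) — and nominated in a dataset when at least two of the
three flags hold. TFs are ranked by the number of datasets nominating them;
the top of the ranking is merged with a manually curated list to form the
final library targets. The motif channel itself is a Fisher exact test of
motif hits in differentially accessible regions against sampled unchanged
control regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_stats import bh_adjust, fisher_exact

__all__ = [
    "Thresholds",
    "AnalysisFlags",
    "NominationRanking",
    "flag_analyses",
    "nominate",
    "rank_and_select",
    "select_control_regions",
    "motif_enrichment",
]


@dataclass(frozen=True)
class Thresholds:
    """Evidence cut-offs; all inequalities are strict."""

    lfc: float = 0.5  # |log2FC| must exceed this (DE and DA)
    fdr: float = 0.05  # FDR must be below this (all channels)
    odds_ratio: float = 1.5  # ME odds ratio must exceed this


@dataclass
class AnalysisFlags:
    """Per (TF, dataset) booleans for DE/DA/ME plus the evidence values."""

    table: pd.DataFrame  # MultiIndex (dataset, tf); columns de, da, me + evidence
    thresholds: Thresholds

    def dataset(self, name: str) -> pd.DataFrame:
        return self.table.xs(name, level="dataset")


@dataclass
class NominationRanking:
    """Ranked TFs with the final-list membership and provenance."""

    table: pd.DataFrame  # index tf; n_datasets_nominated, rank, in_final, source
    top_n: int

    @property
    def final_tfs(self) -> list[str]:
        return list(self.table.index[self.table["in_final"]])

    @property
    def n_final(self) -> int:
        return int(self.table["in_final"].sum())

    @property
    def n_ranked(self) -> int:
        return int(
            (self.table["in_final"] & (self.table["source"] == "ranked")).sum()
        )


def flag_analyses(
    dataset_tables: Mapping[str, Mapping[str, pd.DataFrame]],
    thresholds: Thresholds | None = None,
) -> AnalysisFlags:
    """Evaluate the three evidence channels per TF per dataset.

    ``dataset_tables`` maps dataset name to a dict with keys "de", "da"
    (frames indexed by TF with columns lfc, fdr) and "me" (odds_ratio,
    fdr). A TF absent from a channel's table gets flag False with evidence
    recorded as NaN.
    """
    thr = thresholds or Thresholds()
    rows = []
    for ds, tables in dataset_tables.items():
        tfs: set[str] = set()
        for key in ("de", "da", "me"):
            if key in tables:
                tfs |= set(tables[key].index)
        for tf in sorted(tfs):
            rec: dict[str, object] = {"dataset": ds, "tf": tf}
            for key in ("de", "da"):
                tab = tables.get(key)
                if tab is not None and tf in tab.index:
                    lfc = float(tab.loc[tf, "lfc"])
                    fdr = float(tab.loc[tf, "fdr"])
                    rec[key] = bool(abs(lfc) > thr.lfc and fdr < thr.fdr)
                    rec[f"{key}_lfc"], rec[f"{key}_fdr"] = lfc, fdr
                else:
                    rec[key] = False
                    rec[f"{key}_lfc"] = rec[f"{key}_fdr"] = np.nan
            tab = tables.get("me")
            if tab is not None and tf in tab.index:
                orr = float(tab.loc[tf, "odds_ratio"])
                fdr = float(tab.loc[tf, "fdr"])
                rec["me"] = bool(orr > thr.odds_ratio and fdr < thr.fdr)
                rec["me_or"], rec["me_fdr"] = orr, fdr
            else:
                rec["me"] = False
                rec["me_or"] = rec["me_fdr"] = np.nan
            rows.append(rec)
    table = pd.DataFrame(rows).set_index(["dataset", "tf"])
    return AnalysisFlags(table=table, thresholds=thr)


def nominate(flags: AnalysisFlags, min_channels: int = 2) -> dict[str, set[str]]:
    """Per dataset, the TFs with at least ``min_channels`` of DE/DA/ME true."""
    out: dict[str, set[str]] = {}
    for ds in flags.table.index.get_level_values("dataset").unique():
        sub = flags.dataset(ds)
        votes = sub[["de", "da", "me"]].sum(axis=1)
        out[ds] = set(sub.index[votes >= min_channels])
    return out


def rank_and_select(
    nominations: Mapping[str, set[str]],
    top_n: int,
    curated_list: Sequence[str] = (),
    flags: AnalysisFlags | None = None,
) -> NominationRanking:
    """Rank nominated TFs across datasets and merge the curated additions.

    TFs are ranked by the number of nominating datasets (descending); ties
    break by total |lfc| evidence across datasets and channels (descending,
    when flags are supplied), then lexicographically. The final list is the
    top_n of the ranking plus curated TFs; a curated TF already ranked in
    the top_n is counted once with source "ranked".
    """
    if top_n < 0:
        raise ValueError("top_n must be non-negative")
    counts: dict[str, int] = {}
    for ds, tfs in nominations.items():
        for tf in tfs:
            counts[tf] = counts.get(tf, 0) + 1
    evidence: dict[str, float] = {tf: 0.0 for tf in counts}
    if flags is not None:
        ev = (
            flags.table[["de_lfc", "da_lfc"]]
            .abs()
            .sum(axis=1)
            .groupby(level="tf")
            .sum()
        )
        for tf in evidence:
            evidence[tf] = float(ev.get(tf, 0.0))
    ranked = sorted(counts, key=lambda tf: (-counts[tf], -evidence[tf], tf))
    if top_n > len(ranked):
        warnings.warn(
            f"top_n={top_n} exceeds {len(ranked)} nominated TFs; taking all"
        )
    selected = ranked[:top_n]
    curated = [tf for tf in dict.fromkeys(curated_list)]  # dedup, keep order
    all_tfs = list(dict.fromkeys(ranked + curated))
    table = pd.DataFrame(
        index=pd.Index(all_tfs, name="tf"),
        data={
            "n_datasets_nominated": [counts.get(tf, 0) for tf in all_tfs],
            "rank": [ranked.index(tf) + 1 if tf in counts else 0 for tf in all_tfs],
            "in_final": [tf in selected or tf in curated for tf in all_tfs],
            "source": [
                "ranked" if tf in selected else ("curated" if tf in curated else "")
                for tf in all_tfs
            ],
        },
    )
    return NominationRanking(table=table, top_n=top_n)


def select_control_regions(
    regions: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    lfc_bound: float = 0.05,
    fdr_bound: float = 0.5,
    two_sided: bool = True,
) -> list[str]:
    """Sample unchanged regions as the motif-test control set.

    A region qualifies when its accessibility is unchanged: |log2FC| below
    ``lfc_bound`` (the literal one-sided reading log2FC < bound is available
    with ``two_sided=False``) and FDR above ``fdr_bound``. Exactly ``n``
    qualifying regions are drawn uniformly without replacement with the
    given seed; if fewer qualify, all are returned with a warning.
    """
    lfc = regions["lfc"]
    crit = (lfc.abs() < lfc_bound) if two_sided else (lfc < lfc_bound)
    qualifying = regions.index[crit & (regions["fdr"] > fdr_bound)]
    if len(qualifying) == 0:
        raise ValueError("no qualifying control regions")
    if len(qualifying) <= n:
        if len(qualifying) < n:
            warnings.warn(
                f"only {len(qualifying)} qualifying regions (< {n}); taking all"
            )
        return list(qualifying)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(qualifying), size=n, replace=False)
    return list(qualifying[np.sort(pick)])


def motif_enrichment(
    hit_matrix: pd.DataFrame,
    test_regions: Sequence[str],
    control_regions: Sequence[str],
    or_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of each motif in test vs control regions.

    ``hit_matrix`` is regions × motifs boolean. Per motif the 2×2 table is
    [[hits in test, misses in test], [hits in control, misses in control]];
    BH across motifs; ``enriched`` flags OR > threshold and FDR < threshold.
    """
    if len(test_regions) == 0 or len(control_regions) == 0:
        raise ValueError("test and control region sets must be non-empty")
    missing = (set(test_regions) | set(control_regions)) - set(hit_matrix.index)
    if missing:
        raise ValueError(f"regions absent from hit matrix: {sorted(missing)[:5]}")
    test = hit_matrix.loc[list(test_regions)].astype(bool)
    ctrl = hit_matrix.loc[list(control_regions)].astype(bool)
    rows = []
    for motif in hit_matrix.columns:
        a = int(test[motif].sum())
        b = int((~test[motif]).sum())
        c = int(ctrl[motif].sum())
        d = int((~ctrl[motif]).sum())
        odds, p = fisher_exact([[a, b], [c, d]])
        rows.append((motif, a, c, odds, p))
    out = pd.DataFrame(
        rows, columns=["motif", "hits_test", "hits_control", "odds_ratio", "p_value"]
    ).set_index("motif")
    out["fdr"] = bh_adjust(out["p_value"])
    out["enriched"] = (out["odds_ratio"] > or_threshold) & (out["fdr"] < fdr_threshold)
    return out
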