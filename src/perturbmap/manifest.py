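"""Dual-guide TF-targeting sgRNA library: construction, serialization, matching.

Each vector carries two sgRNAs against the same gene (or two non-targeting
controls). Four guides per gene are distributed over two constructs; capture
reads are matched back to guides by the GGG<protospacer>GTTT anchor pattern
that flanks both spacers in the direct-capture cassette.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "GuideRecord",
    "DualGuideConstruct",
    "LibraryManifest",
    "build_manifest",
    "render_oligo",
    "match_capture_read",
    "read_manifest_tsv",
    "write_manifest_tsv",
    "write_oligo_fasta",
]

logger = logging.getLogger(__name__)

NTC = "NTC"
DNA_ALPHABET = set("ACGT")

# Fixed linker sequences of the dual-guide direct-capture cassette
LINKER_5P = "CCACCTTGTTGG"
LINKER_MID = "GTTTCAGAGCAGTCTTCGTTTTCGGGGAAGACAAGAAACATGG"
LINKER_3P = "GTTTAAGAGCTAAGC"

CAPTURE_LEFT = "GGG"
CAPTURE_RIGHT = "GTTT"


def _check_dna(seq: str, what: str, min_len: int = 1, max_len: int | None = None) -> None:
    if not set(seq) <= DNA_ALPHABET:
        raise ValueError(f"{what} {seq!r} contains non-ACGT characters")
    if len(seq) < min_len or (max_len is not None and len(seq) > max_len):
        raise ValueError(f"{what} {seq!r} has invalid length {len(seq)}")


@dataclass(frozen=True)
class GuideRecord:
    guide_id: str
    protospacer: str
    target: str  # gene symbol or "NTC"
    position_in_construct: str  # "A" or "B"

    def __post_init__(self) -> None:
        _check_dna(self.protospacer, "protospacer", 19, 21)
        if self.position_in_construct not in ("A", "B"):
            raise ValueError("position_in_construct must be 'A' or 'B'")


@dataclass(frozen=True)
class DualGuideConstruct:
    construct_id: str
    guide_a: GuideRecord
    guide_b: GuideRecord
    target: str

    def __post_init__(self) -> None:
        if not (self.guide_a.target == self.guide_b.target == self.target):
            raise ValueError(
                f"construct {self.construct_id}: both guides must target {self.target}"
            )


@dataclass
class LibraryManifest:
    constructs: list[DualGuideConstruct]
    guides_per_gene: int = 4
    guides_per_construct: int = 2
    ntc_constructs: int = 0

    def __post_init__(self) -> None:
        spacers: dict[str, str] = {}
        ids: set[str] = set()
        for con in self.constructs:
            for g in (con.guide_a, con.guide_b):
                if g.guide_id in ids:
                    raise ValueError(f"duplicate guide id {g.guide_id}")
                ids.add(g.guide_id)
                if g.protospacer in spacers:
                    raise ValueError(
                        f"duplicate protospacer shared by {spacers[g.protospacer]} "
                        f"and {g.guide_id}"
                    )
                spacers[g.protospacer] = g.guide_id
        self._spacer_to_guide = spacers

    @property
    def guides(self) -> list[GuideRecord]:
        out = []
        for con in self.constructs:
            out.extend([con.guide_a, con.guide_b])
        return out

    @property
    def targets(self) -> list[str]:
        """Distinct gene-level targets (NTC included if present), input order."""
        seen: dict[str, None] = {}
        for con in self.constructs:
            seen.setdefault(con.target, None)
        return list(seen)

    @property
    def gene_targets(self) -> list[str]:
        return [t for t in self.targets if t != NTC]

    def guide_lookup(self) -> dict[str, GuideRecord]:
        return {g.guide_id: g for g in self.guides}

    def construct_of_guide(self) -> dict[str, str]:
        out = {}
        for con in self.constructs:
            out[con.guide_a.guide_id] = con.construct_id
            out[con.guide_b.guide_id] = con.construct_id
        return out

    def summary(self) -> dict[str, int]:
        gene_cons = [c for c in self.constructs if c.target != NTC]
        ntc_cons = [c for c in self.constructs if c.target == NTC]
        return {
            "n_genes": len({c.target for c in gene_cons}),
            "n_gene_constructs": len(gene_cons),
            "n_gene_sgRNAs": 2 * len(gene_cons),
            "n_ntc_constructs": len(ntc_cons),
            "n_ntc_sgRNAs": 2 * len(ntc_cons),
        }


def build_manifest(
    targets: Sequence[str],
    guide_source: Mapping[str, Sequence[str]],
    guides_per_gene: int = 4,
    guides_per_construct: int = 2,
    ntc_constructs: int = 40,
    ntc_protospacers: Sequence[str] | None = None,
) -> LibraryManifest:
    """Assemble the dual-guide library from per-gene protospacer lists.

    Guides are assigned to constructs in input order (guides 1+2 on the first
    construct, 3+4 on the second), so the library is a deterministic function
    of its inputs. NTC guides are paired the same way.
    """
    if guides_per_construct != 2:
        raise ValueError("dual-guide constructs carry exactly 2 guides")
    if guides_per_gene % guides_per_construct != 0:
        raise ValueError("guides_per_gene must be a multiple of guides_per_construct")
    cons_per_gene = guides_per_gene // guides_per_construct

    constructs: list[DualGuideConstruct] = []
    for gene in targets:
        if gene == NTC:
            raise ValueError("NTC is not a gene target; use ntc_constructs")
        spacers = list(guide_source.get(gene, []))
        if len(spacers) < guides_per_gene:
            raise ValueError(
                f"gene {gene}: {len(spacers)} protospacers supplied, "
                f"{guides_per_gene} required"
            )
        spacers = spacers[:guides_per_gene]
        for k in range(cons_per_gene):
            a_idx, b_idx = 2 * k, 2 * k + 1
            ga = GuideRecord(f"{gene}_g{a_idx + 1}", spacers[a_idx], gene, "A")
            gb = GuideRecord(f"{gene}_g{b_idx + 1}", spacers[b_idx], gene, "B")
            constructs.append(
                DualGuideConstruct(f"{gene}_c{k + 1}", ga, gb, gene)
            )

    if ntc_constructs:
        ntc_spacers = list(ntc_protospacers or [])
        need = ntc_constructs * guides_per_construct
        if len(ntc_spacers) < need:
            raise ValueError(
                f"{need} NTC protospacers required, {len(ntc_spacers)} supplied"
            )
        for k in range(ntc_constructs):
            a_idx, b_idx = 2 * k, 2 * k + 1
            ga = GuideRecord(f"NTC_g{a_idx + 1}", ntc_spacers[a_idx], NTC, "A")
            gb = GuideRecord(f"NTC_g{b_idx + 1}", ntc_spacers[b_idx], NTC, "B")
            constructs.append(DualGuideConstruct(f"NTC_c{k + 1}", ga, gb, NTC))

    return LibraryManifest(
        constructs,
        guides_per_gene=guides_per_gene,
        guides_per_construct=guides_per_construct,
        ntc_constructs=ntc_constructs,
    )


def render_oligo(
    construct: DualGuideConstruct, adapters: tuple[str, str] = ("", "")
) -> str:
    """Render the ordered oligo for one construct.

    Layout: 5'-adapter - CCACCTTGTTGG - protospacer A -
    GTTTCAGAGCAGTCTTCGTTTTCGGGGAAGACAAGAAACATGG - protospacer B -
    GTTTAAGAGCTAAGC - adapter-3'.
    """
    left, right = adapters
    for ad in (left, right):
        if ad and not set(ad) <= DNA_ALPHABET:
            raise ValueError(f"adapter {ad!r} contains non-ACGT characters")
    return (
        left
        + LINKER_5P
        + construct.guide_a.protospacer
        + LINKER_MID
        + construct.guide_b.protospacer
        + LINKER_3P
        + right
    )


def match_capture_read(read_sequence: str, manifest: LibraryManifest) -> str | None:
    """Match a direct-capture read to a guide via the GGG(spacer)GTTT pattern.

    Returns the unique matching guide_id, or None when no protospacer (or
    more than one distinct guide's protospacer) occurs flanked by GGG…GTTT.
    Matching is exact substring, no mismatch tolerance.
    """
    read = read_sequence.upper()
    hits: set[str] = set()
    for spacer, guide_id in manifest._spacer_to_guide.items():
        start = 0
        pattern = CAPTURE_LEFT + spacer + CAPTURE_RIGHT
        if pattern in read:
            hits.add(guide_id)
    if not hits:
        return None
    if len(hits) > 1:
        logger.warning(
            "ambiguous capture read matches %d guides: %s", len(hits), sorted(hits)
        )
        return None
    return hits.pop()


# ---------------------------------------------------------------------------
# Serialization

_MANIFEST_COLUMNS = [
    "construct_id",
    "target",
    "guide_a_id",
    "guide_a_seq",
    "guide_b_id",
    "guide_b_seq",
]


def write_manifest_tsv(manifest: LibraryManifest, path: str | Path) -> None:
    rows = [
        {
            "construct_id": c.construct_id,
            "target": c.target,
            "guide_a_id": c.guide_a.guide_id,
            "guide_a_seq": c.guide_a.protospacer,
            "guide_b_id": c.guide_b.guide_id,
            "guide_b_seq": c.guide_b.protospacer,
        }
        for c in manifest.constructs
    ]
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path: str | Path, **design) -> LibraryManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    constructs = []
    for row in df.itertuples(index=False):
        ga = GuideRecord(row.guide_a_id, row.guide_a_seq, row.target, "A")
        gb = GuideRecord(row.guide_b_id, row.guide_b_seq, row.target, "B")
        constructs.append(DualGuideConstruct(row.construct_id, ga, gb, row.target))
    ntc = sum(1 for c in constructs if c.target == NTC)
    design.setdefault("ntc_constructs", ntc)
    return LibraryManifest(constructs, **design)


def write_oligo_fasta(
    manifest: LibraryManifest,
    path: str | Path,
    adapters: tuple[str, str] = ("", ""),
) -> None:
    with open(path, "w") as fh:
        for con in manifest.constructs:
            fh.write(f">{con.construct_id}\n{render_oligo(con, adapters)}\n")
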