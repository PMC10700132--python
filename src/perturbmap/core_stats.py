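"""Shared numerical primitives for screen analysis.

Count-matrix I/O (MatrixMarket triplet dialect), log-normalization of UMI
counts, the two-sided Wilcoxon rank-sum test, Benjamini–Hochberg adjustment,
and Fisher's exact test. Everything downstream (differential expression,
enrichment, library design) builds on these.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "TestResult",
    "read_count_matrix",
    "write_count_matrix",
    "log_normalize",
    "rank_sum_test",
    "bh_adjust",
    "fisher_exact",
]

FeatureKind = Literal["gene", "sgRNA", "region"]


class FormatError(ValueError):
    """Raised when an on-disk matrix triplet is internally inconsistent."""


@dataclass
class CountMatrix:
    """Cells × features matrix of non-negative integer UMI counts.

    ``values`` is stored as a CSR sparse matrix; ``cell_ids`` and
    ``feature_ids`` must be unique and match the matrix dimensions.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    feature_kind: FeatureKind = "gene"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise FormatError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if m != len(self.feature_ids):
            raise FormatError(
                f"matrix has {m} columns but {len(self.feature_ids)} feature ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("cell ids are not unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("feature ids are not unique")
        data = self.values.data
        if data.size and (data < 0).any():
            raise ValueError("counts must be non-negative")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integral")
        self.values.data = np.asarray(np.round(data), dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, keep: Sequence[str]) -> "CountMatrix":
        index = {c: i for i, c in enumerate(self.cell_ids)}
        rows = [index[c] for c in keep]
        return CountMatrix(
            self.values[rows],
            list(keep),
            list(self.feature_ids),
            self.feature_kind,
        )


@dataclass
class NormalizedMatrix:
    """Cells × genes log-normalized expression: ln(1 + count/total × scale)."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    scale_factor: float = 1e6

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("normalized matrix dimensions inconsistent with ids")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None


@dataclass
class TestResult:
    statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_ids(path: Path) -> list[str]:
    with _open_text(Path(path)) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_count_matrix(
    matrix_path: str | Path,
    cells_path: str | Path,
    features_path: str | Path,
    feature_kind: FeatureKind = "gene",
) -> CountMatrix:
    """Read an MTX + barcodes + features triplet (droplet pipeline dialect).

    The MTX file stores features × cells (the 10x convention); the returned
    matrix is transposed to cells × features.
    """
    mat = mmread(str(matrix_path))
    cells = _read_ids(Path(cells_path))
    features = _read_ids(Path(features_path))
    n_feat, n_cell = mat.shape
    if n_feat != len(features):
        raise FormatError(
            f"MTX declares {n_feat} features but features file has {len(features)}"
        )
    if n_cell != len(cells):
        raise FormatError(
            f"MTX declares {n_cell} cells but barcodes file has {len(cells)}"
        )
    return CountMatrix(sp.csr_matrix(mat.T), cells, features, feature_kind)


def write_count_matrix(
    counts: CountMatrix,
    matrix_path: str | Path,
    cells_path: str | Path,
    features_path: str | Path,
) -> None:
    """Write the triplet; inverse of :func:`read_count_matrix`."""
    mmwrite(str(matrix_path), sp.coo_matrix(counts.values.T), field="integer")
    Path(cells_path).write_text("".join(c + "\n" for c in counts.cell_ids))
    Path(features_path).write_text("".join(f + "\n" for f in counts.feature_ids))


def log_normalize(counts: CountMatrix, scale_factor: float = 1e6) -> NormalizedMatrix:
    """Library-size normalize and log-transform: ln(1 + c_gj/C_j × scale).

    Matches the standard per-cell normalization of droplet scRNA-seq with a
    counts-per-million scale factor. Cells with zero total count map to
    all-zero rows (with a warning) rather than raising.
    """
    if counts.feature_kind != "gene":
        raise ValueError("log_normalize expects a gene-kind count matrix")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = counts.cell_totals().astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} cell(s) with zero total count mapped to zero rows"
        )
    safe_totals = np.where(zero, 1.0, totals)
    dense = counts.to_dense().astype(float)
    values = np.log1p(dense / safe_totals[:, None] * scale_factor)
    values[zero, :] = 0.0
    return NormalizedMatrix(values, list(counts.cell_ids), list(counts.feature_ids), scale_factor)


# ---------------------------------------------------------------------------
# Rank-sum test


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all rank assignments (small n+m)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    total = 0
    extreme = 0
    for comb in combinations(range(len(pooled)), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-9:
            extreme += 1
    return extreme / total


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration of all C(n+m, n) rank splits when n + m ≤ 12; the
    tie-corrected normal approximation with a 0.5 continuity correction
    otherwise. The signed statistic is W − E[W] for sample ``x``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")
    n, m = x.size, y.size
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0
    statistic = w - mu
    if n + m <= 12:
        p = _exact_rank_sum_p(x, y)
    else:
        nm = n + m
        tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)[1]
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((nm) * (nm - 1))
        var = n * m / 12.0 * ((nm + 1) - tie_term)
        if var <= 0:
            return TestResult(statistic=float(statistic), p_value=1.0)
        z = (abs(statistic) - 0.5) / np.sqrt(var)
        z = max(z, 0.0)
        p = 2.0 * stats.norm.sf(z)
    return TestResult(statistic=float(statistic), p_value=float(min(p, 1.0)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    adjusted[i] = min over j with p(j) ≥ p(i) of p(j)·m/rank(j), clipped at 1.
    Ties are resolved by stable sort on input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fisher_exact(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Two-tailed Fisher's exact test on a 2×2 contingency table.

    Returns ``(odds_ratio, p_value)`` where the odds ratio is the sample
    ratio ad/bc. When a zero cell makes ad/bc undefined (0/0 or x/0), the
    Haldane–Anscombe 0.5 correction is applied to every cell for the odds
    ratio only, and a warning flags it. The p-value sums hypergeometric
    probabilities no larger than that of the observed table.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2×2 table")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("table entries must be integers")
    a, b, c, d = t.ravel()
    if b * c == 0:
        # ad/bc undefined: Haldane–Anscombe 0.5 correction, flagged
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        warnings.warn("zero cell: Haldane-corrected odds ratio reported")
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return float(odds), float(p)
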