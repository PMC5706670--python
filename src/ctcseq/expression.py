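"""Per-cell expression quantification (FPKM), Spearman correlation structure,
and marker-panel cell classification.

FPKM (fragments per kilobase of exon per million mapped fragments) normalizes
a gene's fragment count by transcript length and per-cell sequencing depth:

    fpkm[g, c] = 1e9 * counts[g, c] / (length_bp[g] * total_fragments[c])

Correlations are Spearman (rank-then-Pearson with average ranks on ties),
computed on log2(FPKM + 1); the log transform is monotone so it leaves
Spearman untouched, but it fixes the scale any downstream distance reuses.

The marker panel is the immunohistochemistry-style CTC rule: EpCAM/KRT7/KRT8
mark epithelial (tumor-like) cells, CD45 (PTPRC) marks leukocytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignments import AlignedReadRecord


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x cells fragment counts plus FPKM and per-cell totals."""

    counts: pd.DataFrame  # genes x cells, int
    fpkm: pd.DataFrame    # genes x cells, float
    total_fragments: pd.Series  # per cell

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, gene_lengths: Mapping[str, int]) -> "ExpressionMatrix":
        totals = counts.sum(axis=0)
        fpkm = compute_fpkm(counts, gene_lengths, totals)
        return cls(counts=counts, fpkm=fpkm, total_fragments=totals)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cells(self) -> list[str]:
        return list(self.counts.columns)

    def log_fpkm(self) -> pd.DataFrame:
        return np.log2(self.fpkm + 1.0)


@dataclass(frozen=True)
class MarkerPanelConfig:
    """The 4-gene CTC classification panel and its expression threshold."""

    epithelial_genes: frozenset = frozenset({"EPCAM", "KRT7", "KRT8"})
    leukocyte_genes: frozenset = frozenset({"CD45"})
    expressed_threshold: float = 1.0

    def __post_init__(self):
        if not self.epithelial_genes or not self.leukocyte_genes:
            raise ExpressionError("marker gene sets must be non-empty")
        if self.epithelial_genes & self.leukocyte_genes:
            raise ExpressionError("marker gene sets must be disjoint")


def count_fragments(
    records: Sequence[AlignedReadRecord],
    gene_ids: Iterable[str],
    cell_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Count fragments per gene per cell.

    A mate pair (same read_id) counts once; an unmated read also counts once.
    Reads mapped to genes outside ``gene_ids`` raise.
    """
    gene_ids = list(gene_ids)
    known = set(gene_ids)
    seen: set[tuple[str, str]] = set()
    tally: dict[tuple[str, str], int] = {}
    cells_seen: dict[str, None] = {}  # insertion-ordered set
    for rec in records:
        if rec.gene_id not in known:
            raise ExpressionError(f"read {rec.read_id} mapped to unknown gene {rec.gene_id}")
        key = (rec.cell_id, rec.read_id)
        if key in seen:
            continue
        seen.add(key)
        cells_seen.setdefault(rec.cell_id)
        ck = (rec.gene_id, rec.cell_id)
        tally[ck] = tally.get(ck, 0) + 1

    if cell_ids is None:
        cell_ids = list(cells_seen)
    counts = pd.DataFrame(0, index=gene_ids, columns=list(cell_ids), dtype=int)
    for (gid, cid), n in tally.items():
        counts.loc[gid, cid] = n
    return counts


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: Mapping[str, int],
    total_fragments: pd.Series | Mapping[str, int],
) -> pd.DataFrame:
    """fpkm[g, c] = 1e9 * counts[g, c] / (length[g] * total[c])."""
    totals = pd.Series(total_fragments)[counts.columns].astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ExpressionError(f"cell {zero.index[0]!r} has no mapped fragments")
    lengths = pd.Series({g: gene_lengths[g] for g in counts.index}, dtype=float)
    if (lengths <= 0).any():
        raise ExpressionError("gene lengths must be positive")
    return 1e9 * counts.div(lengths, axis=0).div(totals, axis=1)


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks on ties).

    Returns NaN (flagged missing) when either input has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ExpressionError("spearman needs two equal-length vectors of length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    r, _ = stats.pearsonr(rx, ry)
    return float(r)


def correlation_matrix(
    expr: ExpressionMatrix | pd.DataFrame,
    cell_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cells x cells Spearman matrix over all genes of log2(FPKM + 1).

    Pairs involving a zero-variance profile are NaN (flagged missing); the
    diagonal is 1 by convention.
    """
    mat = expr.log_fpkm() if isinstance(expr, ExpressionMatrix) else expr
    if cell_subset is not None:
        mat = mat[list(cell_subset)]
    if mat.shape[1] < 2:
        raise ExpressionError("correlation_matrix needs >= 2 cells")
    corr = mat.corr(method="spearman")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def group_correlation_summary(
    corr: pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Mean +/- SD of off-diagonal correlations within and between groups.

    ``groups`` maps cell_id -> group label. Returns a table with one row per
    (group_a, group_b) pair, a <= b; within-group rows use only off-diagonal
    entries.
    """
    labels = sorted(set(groups.values()))
    rows = []
    cells = list(corr.index)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            vals = []
            for ci in cells:
                for cj in cells:
                    if ci >= cj:
                        continue
                    pair = tuple(sorted((groups.get(ci), groups.get(cj))))
                    if pair == tuple(sorted((a, b))):
                        v = corr.loc[ci, cj]
                        if np.isfinite(v):
                            vals.append(float(v))
            if vals:
                rows.append(
                    {
                        "group_a": a,
                        "group_b": b,
                        "n_pairs": len(vals),
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def pool_bulk_profile(
    counts: pd.DataFrame,
    cell_ids: Sequence[str],
    gene_lengths: Mapping[str, int],
    label: str = "bulk",
) -> pd.DataFrame:
    """Pool k cells' fragments into one bulk FPKM profile (one column)."""
    pooled = counts[list(cell_ids)].sum(axis=1).to_frame(label)
    return compute_fpkm(pooled, gene_lengths, pooled.sum(axis=0))


def classify_cell(
    fpkm_column: Mapping[str, float] | pd.Series,
    panel: MarkerPanelConfig = MarkerPanelConfig(),
) -> str:
    """Assign epithelial / leukocyte / atypical from the 4-gene marker panel.

    epithelial: >= 2 epithelial markers at or above threshold AND every
    leukocyte marker below it; leukocyte: every leukocyte marker at or above
    threshold AND every epithelial marker below it; anything else atypical.
    """
    col = dict(fpkm_column)
    for g in panel.epithelial_genes | panel.leukocyte_genes:
        if g not in col:
            raise ExpressionError(f"marker gene {g} missing from expression matrix")
    t = panel.expressed_threshold
    n_epi = sum(col[g] >= t for g in panel.epithelial_genes)
    leuko_on = all(col[g] >= t for g in panel.leukocyte_genes)
    leuko_off = all(col[g] < t for g in panel.leukocyte_genes)
    epi_off = all(col[g] < t for g in panel.epithelial_genes)
    if n_epi >= 2 and leuko_off:
        return "epithelial"
    if leuko_on and epi_off:
        return "leukocyte"
    return "atypical"


def classify_matrix(expr: ExpressionMatrix, panel: MarkerPanelConfig = MarkerPanelConfig()) -> pd.Series:
    return pd.Series(
        {c: classify_cell(expr.fpkm[c], panel) for c in expr.cells}, name="label"
    )
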