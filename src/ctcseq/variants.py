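"""Per-cell variant profiles at listed SNP sites, deletion detection from
gapped reads, and the cell-cell variant distance.

The screen is site-restricted: only listed (gene, position, ref, alt) sites
are counted, mirroring how a known somatic-mutation catalogue is intersected
with transcriptomic pileups. Third-allele reads count toward depth but toward
neither allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignedReadRecord, PileupColumn, pileup_by_position
from .reference import DeletionTruth, SNPSite

GENOTYPE_CODES = {"uncovered": -1, "ref": 0, "het": 1, "hom_alt": 2}
CODE_TO_GENOTYPE = {v: k for k, v in GENOTYPE_CODES.items()}


class VariantError(ValueError):
    pass


@dataclass
class VariantMatrix:
    """Sites x cells depth / allele counts with coverage and mutant flags.

    ``covered`` is depth >= min_depth (min_depth 1 is the weakest reading of
    "has coverage" and the one the detection-regression heuristic presumes);
    ``mutant_observed`` is alt_count >= min_alt_reads.
    """

    sites: list[SNPSite]
    cells: list[str]
    depth: np.ndarray      # sites x cells, int
    ref_count: np.ndarray
    alt_count: np.ndarray
    min_depth: int = 1
    min_alt_reads: int = 1

    def __post_init__(self):
        if (self.ref_count + self.alt_count > self.depth).any():
            raise VariantError("ref_count + alt_count exceeds depth")

    @property
    def covered(self) -> np.ndarray:
        return self.depth >= self.min_depth

    @property
    def mutant_observed(self) -> np.ndarray:
        return self.alt_count >= self.min_alt_reads

    def site_index(self, site: SNPSite | tuple[str, int]) -> int:
        key = site.key if isinstance(site, SNPSite) else tuple(site)
        for i, s in enumerate(self.sites):
            if s.key == key:
                return i
        raise VariantError(f"site {key} not in matrix")

    def site_summary(self) -> pd.DataFrame:
        """Per-site fraction of cells covered and mean alt fraction among
        covered cells (the two axes of a coverage-vs-mutation display)."""
        cov = self.covered
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_frac = np.where(
                self.ref_count + self.alt_count > 0,
                self.alt_count / np.maximum(self.ref_count + self.alt_count, 1),
                np.nan,
            )
        rows = []
        for i, s in enumerate(self.sites):
            among = alt_frac[i][cov[i]]
            rows.append(
                {
                    "gene_id": s.gene_id,
                    "position": s.position,
                    "fraction_covered": float(cov[i].mean()) if len(self.cells) else 0.0,
                    "mean_alt_fraction": float(np.nanmean(among)) if among.size else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def genotype_codes(
        self,
        min_depth: int = 3,
        het_band: tuple[float, float] = (0.2, 0.8),
    ) -> np.ndarray:
        """Sites x cells genotype codes (-1 uncovered, 0 ref, 1 het, 2 hom_alt)."""
        codes = np.zeros(self.depth.shape, dtype=np.int8)
        codes[self.depth < min_depth] = -1
        allelic = self.ref_count + self.alt_count
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(allelic > 0, self.alt_count / np.maximum(allelic, 1), 0.0)
        lo, hi = het_band
        codes[(self.depth >= min_depth) & (vaf > hi)] = 2
        codes[(self.depth >= min_depth) & (vaf >= lo) & (vaf <= hi)] = 1
        return codes

    def long_table(self, min_depth: int = 3, het_band=(0.2, 0.8)) -> pd.DataFrame:
        codes = self.genotype_codes(min_depth, het_band)
        rows = []
        for i, s in enumerate(self.sites):
            for j, c in enumerate(self.cells):
                rows.append(
                    {
                        "cell": c,
                        "gene": s.gene_id,
                        "pos": s.position,
                        "depth": int(self.depth[i, j]),
                        "ref": int(self.ref_count[i, j]),
                        "alt": int(self.alt_count[i, j]),
                        "genotype": CODE_TO_GENOTYPE[int(codes[i, j])],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DeletionCall:
    """Deletion evidence for one cell over one interval."""

    cell_id: str
    region: DeletionTruth
    spanning_reads: int
    gap_reads: int
    called: bool
    note: str = ""


def site_counts(
    pileup: Mapping[int, PileupColumn] | Sequence[PileupColumn],
    site: SNPSite,
) -> tuple[int, int, int]:
    """(depth, ref_count, alt_count) at a site; (0, 0, 0) if uncovered."""
    columns = pileup if isinstance(pileup, Mapping) else pileup_by_position(pileup)
    col = columns.get(site.position)
    if col is None:
        return (0, 0, 0)
    return (col.depth, col.base_counts[site.ref_base], col.base_counts[site.alt_base])


def build_variant_matrix(
    pileups_by_cell: Mapping[str, Mapping[str, Mapping[int, PileupColumn] | Sequence[PileupColumn]]],
    sites: Sequence[SNPSite],
    min_depth: int = 1,
    min_alt_reads: int = 1,
) -> VariantMatrix:
    """Assemble the sites x cells variant matrix from per-cell, per-gene pileups."""
    if min_depth < 1 or min_alt_reads < 1:
        raise VariantError("min_depth and min_alt_reads must be >= 1")
    keys = [s.key for s in sites]
    if len(set(keys)) != len(keys):
        raise VariantError("duplicate SNP sites")
    cells = list(pileups_by_cell)
    shape = (len(sites), len(cells))
    depth = np.zeros(shape, dtype=np.int64)
    ref = np.zeros(shape, dtype=np.int64)
    alt = np.zeros(shape, dtype=np.int64)
    for j, cell in enumerate(cells):
        gene_pileups = pileups_by_cell[cell]
        normalized = {
            g: (p if isinstance(p, Mapping) else pileup_by_position(p))
            for g, p in gene_pileups.items()
        }
        for i, s in enumerate(sites):
            d, r, a = site_counts(normalized.get(s.gene_id, {}), s)
            depth[i, j], ref[i, j], alt[i, j] = d, r, a
    return VariantMatrix(
        sites=list(sites), cells=cells, depth=depth, ref_count=ref,
        alt_count=alt, min_depth=min_depth, min_alt_reads=min_alt_reads,
    )


def genotype_call(
    depth: int,
    ref_count: int,
    alt_count: int,
    min_depth: int = 3,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> str:
    """Threshold genotype call from site counts.

    uncovered if depth < min_depth; else VAF = alt/(ref+alt) (0 when both 0);
    hom_alt above the het band, het inside it (inclusive), ref below.
    """
    if depth < min_depth:
        return "uncovered"
    allelic = ref_count + alt_count
    vaf = alt_count / allelic if allelic > 0 else 0.0
    lo, hi = het_band
    if vaf > hi:
        return "hom_alt"
    if vaf >= lo:
        return "het"
    return "ref"


def detect_deletion(
    records_for_cell: Sequence[AlignedReadRecord],
    region: DeletionTruth,
    min_gap_reads: int = 2,
    min_gap_fraction: float = 0.2,
    cell_id: str | None = None,
) -> DeletionCall:
    """Call a deletion from gapped reads over a candidate interval.

    A read spans the region if its reference span touches it; it is a gap
    read if one of its deletion segments overlaps the region by at least half
    the region length. Called iff gap_reads >= min_gap_reads and the gap
    fraction among spanning reads >= min_gap_fraction.
    """
    spanning = gap = 0
    cid = cell_id or (records_for_cell[0].cell_id if records_for_cell else "")
    half = 0.5 * region.length
    for rec in records_for_cell:
        if rec.gene_id != region.gene_id:
            continue
        if rec.end <= region.start or rec.start >= region.end:
            continue
        spanning += 1
        for ds, de in rec.deletion_intervals():
            if min(de, region.end) - max(ds, region.start) >= half:
                gap += 1
                break
    if spanning == 0:
        return DeletionCall(cid, region, 0, 0, False, note="no coverage")
    called = gap >= min_gap_reads and gap / spanning >= min_gap_fraction
    return DeletionCall(cid, region, spanning, gap, called)


# ------------------------------------------------------------ variant distance

# discordance weights between genotype codes (0 ref, 1 het, 2 hom_alt):
# het<->hom counts 0.5 (one allele apart), ref<->non-ref counts 1.
_W = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 0.5], [1.0, 0.5, 0.0]])


def variant_distance(
    codes_i: np.ndarray,
    codes_j: np.ndarray,
    min_shared_sites: int = 5,
) -> float:
    """Mean weighted genotype discordance over sites covered in both cells.

    NaN (flagged missing) when fewer than ``min_shared_sites`` sites are
    covered in both cells.
    """
    gi = np.asarray(codes_i)
    gj = np.asarray(codes_j)
    shared = (gi >= 0) & (gj >= 0)
    n = int(shared.sum())
    if n < min_shared_sites:
        return float("nan")
    return float(_W[gi[shared], gj[shared]].mean())


def pairwise_variant_distances(
    codes: np.ndarray,
    cells: Sequence[str],
    min_shared_sites: int = 5,
) -> pd.DataFrame:
    """Cells x cells weighted-discordance distance matrix from genotype codes.

    Vectorized over the 3x3 genotype-pair weight table; missing pairs (too
    few shared covered sites) are NaN.
    """
    valid = codes >= 0
    n_shared = valid.astype(np.int64).T @ valid.astype(np.int64)
    num = np.zeros((codes.shape[1], codes.shape[1]))
    for a in range(3):
        ia = ((codes == a) & valid).astype(np.float64)
        for b in range(3):
            w = _W[a, b]
            if w == 0.0:
                continue
            ib = ((codes == b) & valid).astype(np.float64)
            num += w * (ia.T @ ib)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(n_shared >= min_shared_sites, num / np.maximum(n_shared, 1), np.nan)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=list(cells), columns=list(cells))
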