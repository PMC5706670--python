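"""Synthetic reference transcriptome: gene models, SNP sites, deletion truths.

The reference is transcript-space: each gene is a single contiguous
single-isoform sequence, so every position is "exonic". This mirrors how
variant screening on expressed isoforms actually consumes coordinates, and
keeps splice structure out of scope.

Coordinates are 0-based, half-open throughout the package; only SAM output
converts to 1-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

MARKER_ROLES = ("epithelial", "leukocyte", "none")


class PanelConfigError(ValueError):
    """Raised when a panel specification is internally inconsistent."""


@dataclass(frozen=True)
class GeneModel:
    """One single-isoform gene: id, transcript length, marker role, sequence."""

    gene_id: str
    transcript_length: int
    marker_role: str = "none"
    sequence: str = ""

    def __post_init__(self):
        if self.transcript_length < 200:
            raise PanelConfigError(
                f"gene {self.gene_id}: transcript_length {self.transcript_length} < 200"
            )
        if self.marker_role not in MARKER_ROLES:
            raise PanelConfigError(
                f"gene {self.gene_id}: unknown marker_role {self.marker_role!r}"
            )
        if self.sequence and len(self.sequence) != self.transcript_length:
            raise PanelConfigError(
                f"gene {self.gene_id}: sequence length {len(self.sequence)} != "
                f"transcript_length {self.transcript_length}"
            )


@dataclass(frozen=True)
class SNPSite:
    """A screened single-nucleotide variant site on a transcript (0-based)."""

    gene_id: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise PanelConfigError(
                f"SNP {self.gene_id}:{self.position}: bases must be one of {BASES}"
            )
        if self.ref_base == self.alt_base:
            raise PanelConfigError(
                f"SNP {self.gene_id}:{self.position}: ref_base equals alt_base"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.position)


@dataclass(frozen=True)
class DeletionTruth:
    """A multi-base deletion interval [start, end) on a transcript."""

    gene_id: str
    start: int
    end: int
    carrier_population: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise PanelConfigError(
                f"deletion {self.gene_id}:{self.start}-{self.end}: invalid interval"
            )
        if self.end - self.start < 3:
            raise PanelConfigError(
                f"deletion {self.gene_id}:{self.start}-{self.end}: shorter than 3 bp"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferencePanel:
    """A built synthetic transcriptome with its truth variant annotation."""

    genes: list[GeneModel]
    snps: list[SNPSite]
    deletions: list[DeletionTruth]
    seed: int

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise PanelConfigError("gene_ids are not unique")
        self._by_id = {g.gene_id: g for g in self.genes}
        seen = set()
        for s in self.snps:
            if s.key in seen:
                raise PanelConfigError(f"duplicate SNP site {s.gene_id}:{s.position}")
            seen.add(s.key)

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def lengths(self) -> dict[str, int]:
        return {g.gene_id: g.transcript_length for g in self.genes}

    def snps_for_gene(self, gene_id: str) -> list[SNPSite]:
        return [s for s in self.snps if s.gene_id == gene_id]

    def deletions_for(self, gene_id: str, population: str) -> list[DeletionTruth]:
        return [
            d for d in self.deletions
            if d.gene_id == gene_id and d.carrier_population == population
        ]

    # ------------------------------------------------------------------ I/O

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}\n")
                for i in range(0, g.transcript_length, 60):
                    fh.write(g.sequence[i : i + 60] + "\n")

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "length": [g.transcript_length for g in self.genes],
                "marker_role": [g.marker_role for g in self.genes],
            }
        )

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [s.gene_id for s in self.snps],
                "position": [s.position for s in self.snps],
                "ref": [s.ref_base for s in self.snps],
                "alt": [s.alt_base for s in self.snps],
            }
        )

    def deletion_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [d.gene_id for d in self.deletions],
                "start": [d.start for d in self.deletions],
                "end": [d.end for d in self.deletions],
                "carrier_population": [d.carrier_population for d in self.deletions],
            }
        )


def build_reference(
    genes: list[GeneModel],
    snps: list[SNPSite] = (),
    deletions: list[DeletionTruth] = (),
    seed: int = 0,
) -> ReferencePanel:
    """Generate sequences for a panel of gene models.

    Sequences are uniform random over {A, C, G, T}; the base at every listed
    SNP position is then forced to the site's ``ref_base`` so that truth
    coincides with the emitted reference. Deterministic given ``seed``.

    Raises
    ------
    PanelConfigError
        If a SNP or deletion falls outside its gene, or a gene is missing.
    """
    lengths = {g.gene_id: g.transcript_length for g in genes}
    for s in snps:
        if s.gene_id not in lengths:
            raise PanelConfigError(f"SNP references unknown gene {s.gene_id}")
        if not (0 <= s.position < lengths[s.gene_id]):
            raise PanelConfigError(
                f"SNP position {s.position} outside gene {s.gene_id} "
                f"(length {lengths[s.gene_id]})"
            )
    for d in deletions:
        if d.gene_id not in lengths:
            raise PanelConfigError(f"deletion references unknown gene {d.gene_id}")
        if d.end > lengths[d.gene_id]:
            raise PanelConfigError(
                f"deletion {d.gene_id}:{d.start}-{d.end} exceeds gene length "
                f"{lengths[d.gene_id]}"
            )

    rng = np.random.default_rng(seed)
    base_arr = np.array(list("ACGT"))
    built = []
    snps_by_gene: dict[str, list[SNPSite]] = {}
    for s in snps:
        snps_by_gene.setdefault(s.gene_id, []).append(s)
    for g in genes:
        codes = rng.integers(0, 4, size=g.transcript_length)
        seq = base_arr[codes]
        for s in snps_by_gene.get(g.gene_id, []):
            seq[s.position] = s.ref_base
        built.append(dataclasses.replace(g, sequence="".join(seq)))
    return ReferencePanel(genes=built, snps=list(snps), deletions=list(deletions), seed=seed)


# ------------------------------------------------------------------ tables in

def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def read_snp_table(path) -> list[SNPSite]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return [
        SNPSite(r.gene_id, int(r.position), r.ref, r.alt)
        for r in df.itertuples(index=False)
    ]


def read_snp_vcf(path) -> list[SNPSite]:
    """Minimal VCF reader for site lists: CHROM = gene_id, 1-based POS, REF, ALT.

    Only single-base REF/ALT records are accepted; other columns are ignored.
    """
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1:
                raise PanelConfigError(
                    f"VCF record {chrom}:{pos}: only single-base SNVs supported"
                )
            sites.append(SNPSite(chrom, int(pos) - 1, ref, alt))
    return sites
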