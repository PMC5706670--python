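"""Simulate mixed cell populations and full-length paired-end alignments.

The generator emulates a circulating-tumor-cell spike-in experiment read out
by a full-length single-cell mRNA-seq chemistry:

* populations (tumor clones, leukocytes) each carry a mean expression profile
  on the FPKM scale, SNP genotypes, and optional multi-base deletions;
* each cell realizes the profile with multiplicative lognormal noise and
  logistic expression-dependent dropout (the standard scRNA-seq bimodality);
* fragments are drawn per gene with probability proportional to
  abundance x transcript length (FPKM-scale abundance times length is
  fragment mass), placed uniformly along the transcript in ``full_length``
  mode, and emitted as two 75 bp mates born aligned to the reference.

Heterozygous variants are phased onto allele 1; each fragment draws its
parental allele with probability 1/2, which jointly governs its het SNP bases
and whether it carries a het deletion. A ``three_prime_biased`` coverage mode
(truncated-exponential fragment starts near the 3' end) exists only as the
contrast to the full-length hypothesis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import AlignedReadRecord, write_sam
from .reference import DeletionTruth, PanelConfigError, ReferencePanel

logger = logging.getLogger(__name__)

ZYGOSITIES = ("ref", "het", "hom_alt")


@dataclass(frozen=True)
class DeletionCarriage:
    """A deletion carried by a population, with its zygosity."""

    region: DeletionTruth
    zygosity: str = "het"

    def __post_init__(self):
        if self.zygosity not in ("het", "hom_alt"):
            raise PanelConfigError(f"deletion zygosity {self.zygosity!r} invalid")


@dataclass(frozen=True)
class PopulationSpec:
    """Population-level truth: expression means, SNP genotypes, deletions.

    ``genotype`` maps (gene_id, position) -> zygosity; unlisted sites are
    homozygous reference.
    """

    label: str
    mean_fpkm: dict[str, float]
    genotype: dict[tuple[str, int], str] = field(default_factory=dict)
    deletions: tuple[DeletionCarriage, ...] = ()

    def __post_init__(self):
        if not any(v > 0 for v in self.mean_fpkm.values()):
            raise PanelConfigError(f"population {self.label}: no expressed gene")
        for key, z in self.genotype.items():
            if z not in ZYGOSITIES:
                raise PanelConfigError(
                    f"population {self.label}: zygosity {z!r} at {key} invalid"
                )


@dataclass(frozen=True)
class SimConfig:
    """Experiment-level simulation parameters.

    Defaults are the study conditions: 75 bp paired-end reads, full-length
    coverage, logistic dropout with midpoint 8 FPKM and slope 1.5, and no
    sequencing errors.
    """

    n_cells_per_population: dict[str, int]
    read_length: int = 75
    fragment_length: int = 200
    fragments_per_cell: int = 200_000
    lognormal_sigma: float = 1.0
    dropout_midpoint_fpkm: float = 8.0
    dropout_slope: float = 1.5
    coverage_mode: str = "full_length"
    error_rate: float = 0.0
    master_seed: int = 0

    def __post_init__(self):
        if self.fragment_length < self.read_length:
            raise PanelConfigError("fragment_length must be >= read_length")
        if self.fragments_per_cell <= 0:
            raise PanelConfigError("fragments_per_cell must be > 0")
        if self.coverage_mode not in ("full_length", "three_prime_biased"):
            raise PanelConfigError(f"unknown coverage_mode {self.coverage_mode!r}")
        for label, n in self.n_cells_per_population.items():
            if n < 0:
                raise PanelConfigError(f"negative cell count for population {label!r}")


@dataclass(frozen=True)
class CellTruth:
    """One simulated cell: realized abundances, dropout outcome, seed."""

    cell_id: str
    population: str
    relative_abundance: dict[str, float]
    n_fragments: int
    seed: int

    def __post_init__(self):
        if not any(v > 0 for v in self.relative_abundance.values()):
            raise PanelConfigError(f"cell {self.cell_id}: all abundances zero")
        if self.n_fragments <= 0:
            raise PanelConfigError(f"cell {self.cell_id}: n_fragments must be > 0")


def dropout_probability(mean_fpkm, midpoint: float, slope: float):
    """Logistic-in-log-expression dropout: p = 1 / (1 + (mean/midpoint)^slope).

    A nonpositive ``midpoint`` disables dropout (p = 0 wherever mean > 0).
    Genes with mean 0 are always absent (p = 1).
    """
    mean = np.asarray(mean_fpkm, dtype=float)
    p = np.ones_like(mean)
    pos = mean > 0
    if midpoint <= 0:
        p[pos] = 0.0
    else:
        p[pos] = 1.0 / (1.0 + (mean[pos] / midpoint) ** slope)
    return p if p.ndim else float(p)


def sample_cells(
    populations: list[PopulationSpec],
    cfg: SimConfig,
    panel: ReferencePanel | None = None,
) -> list[CellTruth]:
    """Realize per-cell abundances for the configured census.

    Cell counts per population are exact (deterministic, not multinomial).
    Per gene g: abundance = mean_fpkm[g] * lognormal(0, sigma) * keep, with
    keep ~ Bernoulli(1 - p_drop(g)). Reproducible from ``cfg.master_seed``;
    each cell records its own child seed.
    """
    labels = [p.label for p in populations]
    if len(set(labels)) != len(labels):
        raise PanelConfigError("population labels are not unique")
    if panel is not None:
        known = set(panel.gene_ids)
        for pop in populations:
            for gid in pop.mean_fpkm:
                if gid not in known:
                    raise PanelConfigError(
                        f"population {pop.label}: unknown gene {gid}"
                    )
            for gid, pos in pop.genotype:
                if gid not in known:
                    raise PanelConfigError(
                        f"population {pop.label}: genotyped site on unknown gene {gid}"
                    )

    ss = np.random.SeedSequence(cfg.master_seed)
    total = sum(cfg.n_cells_per_population.get(p.label, 0) for p in populations)
    children = ss.spawn(total)
    cells: list[CellTruth] = []
    k = 0
    for pop in populations:
        n = cfg.n_cells_per_population.get(pop.label, 0)
        gene_ids = list(pop.mean_fpkm)
        means = np.array([pop.mean_fpkm[g] for g in gene_ids], dtype=float)
        p_drop = dropout_probability(means, cfg.dropout_midpoint_fpkm, cfg.dropout_slope)
        for i in range(n):
            seed = int(children[k].generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
            k += 1
            rng = np.random.default_rng(seed)
            noise = (
                np.exp(rng.normal(0.0, cfg.lognormal_sigma, size=len(means)))
                if cfg.lognormal_sigma > 0
                else np.ones(len(means))
            )
            keep = rng.random(len(means)) >= p_drop
            abundance = means * noise * keep
            # a cell must transcribe something; condition the dropout draw on
            # at least one surviving gene (redraw from the same stream)
            while not np.any(abundance > 0):
                keep = rng.random(len(means)) >= p_drop
                abundance = means * noise * keep
            cells.append(
                CellTruth(
                    cell_id=f"{pop.label}_{i:03d}",
                    population=pop.label,
                    relative_abundance=dict(zip(gene_ids, abundance.tolist())),
                    n_fragments=cfg.fragments_per_cell,
                    seed=seed,
                )
            )
    return cells


# ----------------------------------------------------------------- read birth

def _allele_sequences(panel: ReferencePanel, pop: PopulationSpec):
    """Per gene: (seq_allele0, seq_allele1, del_allele0, del_allele1).

    Alt bases are substituted per zygosity (hom_alt: both alleles; het:
    allele 1 only); a deletion removes its interval from the carrying
    allele's transcript.
    """
    dels: dict[str, DeletionCarriage] = {}
    for carriage in pop.deletions:
        gid = carriage.region.gene_id
        if gid in dels:
            raise PanelConfigError(
                f"population {pop.label}: more than one deletion on gene {gid}"
            )
        if carriage.region.end > panel.gene(gid).transcript_length:
            raise PanelConfigError(
                f"population {pop.label}: deletion outside gene {gid}"
            )
        dels[gid] = carriage

    out = {}
    snps_by_gene: dict[str, list] = {}
    for site in panel.snps:
        z = pop.genotype.get(site.key, "ref")
        if z != "ref":
            snps_by_gene.setdefault(site.gene_id, []).append((site, z))
    for gene in panel.genes:
        a0 = list(gene.sequence)
        a1 = list(gene.sequence)
        for site, z in snps_by_gene.get(gene.gene_id, []):
            a1[site.position] = site.alt_base
            if z == "hom_alt":
                a0[site.position] = site.alt_base
        d0 = d1 = None
        carriage = dels.get(gene.gene_id)
        if carriage is not None:
            region = carriage.region
            d1 = region
            a1 = a1[: region.start] + a1[region.end :]
            if carriage.zygosity == "hom_alt":
                d0 = region
                a0 = a0[: region.start] + a0[region.end :]
        out[gene.gene_id] = ("".join(a0), "".join(a1), d0, d1)
    return out


def _fragment_starts(rng, n, allele_len, cfg: SimConfig):
    """Fragment start positions on the allele transcript."""
    span = allele_len - cfg.fragment_length
    if cfg.coverage_mode == "full_length":
        return rng.integers(0, span + 1, size=n)
    # three_prime_biased: distance from the 3' end ~ truncated Exp(rate 3/L)
    scale = allele_len / 3.0
    u = rng.random(n)
    trunc = 1.0 - np.exp(-span / scale)
    d = -scale * np.log1p(-u * trunc)
    return span - np.minimum(d.astype(int), span)


def _interval_to_segments(a0: int, a1: int, deletion: DeletionTruth | None):
    """Map an allele-coordinate interval [a0, a1) to reference start + CIGAR."""
    if deletion is None:
        return a0, (("M", a1 - a0),)
    ds, dlen = deletion.start, deletion.length
    if a1 <= ds:
        return a0, (("M", a1 - a0),)
    if a0 >= ds:
        return a0 + dlen, (("M", a1 - a0),)
    return a0, (("M", ds - a0), ("D", dlen), ("M", a1 - ds))


def simulate_reads(
    cell: CellTruth,
    panel: ReferencePanel,
    population: PopulationSpec,
    cfg: SimConfig,
) -> list[AlignedReadRecord]:
    """Emit the cell's aligned 75 bp mate pairs, deterministic given cell.seed.

    Genes shorter than the fragment length are excluded with a logged
    warning; genes with zero abundance emit nothing.
    """
    allele_data = _allele_sequences(panel, population)
    gene_ids, weights = [], []
    for gid, abundance in cell.relative_abundance.items():
        if abundance <= 0:
            continue
        length = panel.gene(gid).transcript_length
        if length < cfg.fragment_length:
            logger.warning(
                "gene %s (length %d) shorter than fragment_length %d; excluded",
                gid, length, cfg.fragment_length,
            )
            continue
        _, a1_seq, _, d1 = allele_data[gid]
        if len(a1_seq) < cfg.fragment_length:
            raise PanelConfigError(
                f"gene {gid}: deleted allele shorter than fragment_length"
            )
        gene_ids.append(gid)
        weights.append(abundance * length)
    if not gene_ids:
        return []

    rng = np.random.default_rng([7, cell.seed])
    p = np.asarray(weights) / np.sum(weights)
    n = cell.n_fragments
    gene_choice = rng.choice(len(gene_ids), size=n, p=p)
    alleles = rng.integers(0, 2, size=n)
    starts = np.empty(n, dtype=int)
    for k, gid in enumerate(gene_ids):
        seq0, seq1, d0, d1 = allele_data[gid]
        for allele, seq in ((0, seq0), (1, seq1)):
            mask = (gene_choice == k) & (alleles == allele)
            cnt = int(mask.sum())
            if cnt:
                starts[mask] = _fragment_starts(rng, cnt, len(seq), cfg)

    records: list[AlignedReadRecord] = []
    R, F = cfg.read_length, cfg.fragment_length
    for i in range(n):
        gid = gene_ids[gene_choice[i]]
        seq0, seq1, d0, d1 = allele_data[gid]
        seq, deletion = (seq1, d1) if alleles[i] else (seq0, d0)
        s = int(starts[i])
        rid = f"{cell.cell_id}.f{i}"
        for mate, (a0, a1) in ((1, (s, s + R)), (2, (s + F - R, s + F))):
            ref_start, segments = _interval_to_segments(a0, a1, deletion)
            records.append(
                AlignedReadRecord(
                    read_id=rid,
                    cell_id=cell.cell_id,
                    gene_id=gid,
                    start=ref_start,
                    segments=segments,
                    mate_flag=mate,
                    seq=seq[a0:a1],
                )
            )
    if cfg.error_rate > 0:
        records = _apply_errors(records, cfg.error_rate, rng)
    return records


def _apply_errors(records, rate, rng):
    """Uniform substitution errors at the given per-base rate."""
    out = []
    bases = "ACGT"
    for rec in records:
        n_err = rng.binomial(len(rec.seq), rate)
        if n_err == 0:
            out.append(rec)
            continue
        seq = list(rec.seq)
        for pos in rng.integers(0, len(seq), size=n_err):
            seq[pos] = bases[(bases.index(seq[pos]) + rng.integers(1, 4)) % 4]
        out.append(
            AlignedReadRecord(
                read_id=rec.read_id, cell_id=rec.cell_id, gene_id=rec.gene_id,
                start=rec.start, segments=rec.segments, mate_flag=rec.mate_flag,
                seq="".join(seq),
            )
        )
    return out


# -------------------------------------------------------------------- dataset

def emit_dataset(
    cells: list[CellTruth],
    panel: ReferencePanel,
    populations: list[PopulationSpec],
    cfg: SimConfig,
    out_dir,
) -> dict:
    """Write the full dataset (FASTA, per-cell SAM, truth tables, manifest).

    Re-running with the same configuration is byte-identical; the manifest
    records a sha256 per file plus all seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pop_by_label = {p.label: p for p in populations}

    files: list[str] = []

    def _register(name):
        files.append(name)
        return out / name

    panel.write_fasta(_register("reference.fasta"))
    panel.gene_table().to_csv(_register("gene_models.tsv"), sep="\t", index=False)
    panel.snp_table().to_csv(_register("snp_sites.tsv"), sep="\t", index=False)
    panel.deletion_table().to_csv(_register("deletions.tsv"), sep="\t", index=False)
    truth = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "population": [c.population for c in cells],
            "n_fragments": [c.n_fragments for c in cells],
            "seed": [c.seed for c in cells],
        }
    )
    truth.to_csv(_register("cell_truth.tsv"), sep="\t", index=False)

    lengths = panel.lengths
    for cell in cells:
        records = simulate_reads(cell, panel, pop_by_label[cell.population], cfg)
        with open(_register(f"{cell.cell_id}.sam"), "w") as fh:
            write_sam(records, lengths, fh, cell_id=cell.cell_id)

    manifest = {
        "master_seed": cfg.master_seed,
        "panel_seed": panel.seed,
        "n_cells": len(cells),
        "cells": [c.cell_id for c in cells],
        "files": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
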