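"""Packaged study conditions: reference panel and experiment configurations.

These are the fixed desk-scale conditions every analysis driver and test
runs against; they emulate a circulating-tumor-cell spike-in with two
NSCLC-like tumor clones and a leukocyte background:

* a 40-gene transcriptome with the 4-gene marker panel (EpCAM, KRT7, KRT8 as
  epithelial markers; CD45 as the leukocyte marker), an EGFR-like gene
  carrying a 15 bp exon-deletion in clone A, and 35 background genes whose
  expression spans the SNP-detection transition zone;
* a catalogue of 55 screened SNP sites: 40 homozygous clone-discriminating
  sites (20 private to each clone), 6 shared homozygous and 4 shared
  heterozygous sites, and 5 catalogue sites absent from every population
  (covered-but-no-mutant pattern);
* three experiment configurations: a noiseless two-clone mixture for variant
  clustering (depth chosen so every site is covered in every cell), a noisy
  mixed tumor/leukocyte population for expression analyses, and a
  single-population detection-gradient experiment for the coverage model.
"""

from __future__ import annotations

import numpy as np

from .reference import DeletionTruth, GeneModel, ReferencePanel, SNPSite, build_reference
from .simulate import DeletionCarriage, PopulationSpec, SimConfig

BACKGROUND_GENES = [f"GENE{i:02d}" for i in range(1, 36)]
MARKER_GENES = ["EPCAM", "KRT7", "KRT8", "CD45", "EGFR"]

EGFR_DELETION = DeletionTruth("EGFR", 1500, 1515, carrier_population="clone_a")

# bases for SNP sites; ref/alt fixed so the panel is reproducible as text
_REF_ALT = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def _gene_length(i: int) -> int:
    return 1200 + 240 * ((i * 3) % 11)


def _background_fpkm() -> dict[str, float]:
    """Log2-spaced means from 0.5 to 64 FPKM across the 35 background genes."""
    exps = np.linspace(-1.0, 6.0, len(BACKGROUND_GENES))
    return {g: float(2.0**e) for g, e in zip(BACKGROUND_GENES, exps)}


def demo_panel(seed: int = 2017) -> ReferencePanel:
    """Build the 40-gene reference with its 55-site SNP catalogue."""
    genes = [
        GeneModel("EPCAM", 1500, "epithelial"),
        GeneModel("KRT7", 1700, "epithelial"),
        GeneModel("KRT8", 1900, "epithelial"),
        GeneModel("CD45", 2200, "leukocyte"),
        GeneModel("EGFR", 3000, "none"),
    ] + [GeneModel(g, _gene_length(i), "none") for i, g in enumerate(BACKGROUND_GENES)]
    lengths = {g.gene_id: g.transcript_length for g in genes}

    snps: list[SNPSite] = []

    def add(gene: str, frac: float, k: int):
        ref, alt = _REF_ALT[k % 4]
        snps.append(SNPSite(gene, int(frac * lengths[gene]), ref, alt))

    for k, g in enumerate(BACKGROUND_GENES[:20]):
        add(g, 0.3, k)        # clone A private, homozygous
        add(g, 0.7, k + 1)    # clone B private, homozygous
    for k, g in enumerate(BACKGROUND_GENES[20:26]):
        add(g, 0.5, k)        # shared homozygous
    for k, g in enumerate(BACKGROUND_GENES[26:30]):
        add(g, 0.5, k)        # shared heterozygous
    for k, g in enumerate(BACKGROUND_GENES[30:35]):
        add(g, 0.5, k)        # in the catalogue, absent from all populations

    return build_reference(genes, snps, deletions=[EGFR_DELETION], seed=seed)


def clone_discriminating_sites(panel: ReferencePanel):
    """(clone A private sites, clone B private sites) as (gene, pos) keys."""
    a_sites, b_sites = [], []
    for g in BACKGROUND_GENES[:20]:
        length = panel.gene(g).transcript_length
        a_sites.append((g, int(0.3 * length)))
        b_sites.append((g, int(0.7 * length)))
    return a_sites, b_sites


def _shared_genotype(panel: ReferencePanel) -> dict[tuple[str, int], str]:
    geno = {}
    for g in BACKGROUND_GENES[20:26]:
        geno[(g, int(0.5 * panel.gene(g).transcript_length))] = "hom_alt"
    for g in BACKGROUND_GENES[26:30]:
        geno[(g, int(0.5 * panel.gene(g).transcript_length))] = "het"
    return geno


def _clone_genotypes(panel: ReferencePanel):
    a_sites, b_sites = clone_discriminating_sites(panel)
    shared = _shared_genotype(panel)
    geno_a = dict(shared)
    geno_b = dict(shared)
    for key in a_sites:
        geno_a[key] = "hom_alt"
    for key in b_sites:
        geno_b[key] = "hom_alt"
    return geno_a, geno_b


def epithelial_profile() -> dict[str, float]:
    prof = {"EPCAM": 120.0, "KRT7": 80.0, "KRT8": 150.0, "CD45": 0.0, "EGFR": 60.0}
    prof.update(_background_fpkm())
    return prof


def leukocyte_profile() -> dict[str, float]:
    prof = {"EPCAM": 0.0, "KRT7": 0.0, "KRT8": 0.0, "CD45": 250.0, "EGFR": 0.0}
    bg = _background_fpkm()
    vals = list(bg.values())[::-1]  # reversed gradient: a distinct phenotype
    prof.update(dict(zip(bg.keys(), vals)))
    return prof


def uniform_high_profile() -> dict[str, float]:
    """All genes well expressed; used when every site must be deeply covered."""
    prof = {"EPCAM": 120.0, "KRT7": 80.0, "KRT8": 150.0, "CD45": 0.0, "EGFR": 60.0}
    prof.update({g: 30.0 + 15.0 * (i % 5) for i, g in enumerate(BACKGROUND_GENES)})
    return prof


def tumor_clones(
    panel: ReferencePanel,
    shared_expression: bool = True,
    high_depth_profile: bool = False,
) -> tuple[PopulationSpec, PopulationSpec]:
    """The two tumor-clone populations.

    With ``shared_expression`` the clones are phenotypically identical and
    differ only in genotype; otherwise clone B gets modest fold-changes on a
    third of background genes (similar but separable expression profiles).
    """
    geno_a, geno_b = _clone_genotypes(panel)
    base = uniform_high_profile() if high_depth_profile else epithelial_profile()
    prof_b = dict(base)
    if not shared_expression:
        for i, g in enumerate(BACKGROUND_GENES):
            if i % 3 == 0:
                prof_b[g] = base[g] * 3.0
            elif i % 3 == 1:
                prof_b[g] = base[g] / 3.0
    clone_a = PopulationSpec(
        label="clone_a",
        mean_fpkm=dict(base),
        genotype=geno_a,
        deletions=(DeletionCarriage(EGFR_DELETION, "het"),),
    )
    clone_b = PopulationSpec(label="clone_b", mean_fpkm=prof_b, genotype=geno_b)
    return clone_a, clone_b


def wbc_population() -> PopulationSpec:
    return PopulationSpec(label="wbc", mean_fpkm=leukocyte_profile())


def two_clone_experiment(seed: int = 11, n_per_clone: int = 20,
                         fragments_per_cell: int = 50_000):
    """Noiseless 1:1 two-clone mixture for variant-profile clustering.

    Clones share the expression phenotype, differ at the 40 discriminating
    sites, and are sequenced deeply enough that every catalogue site is
    covered in every cell.
    """
    panel = demo_panel(seed=2017)
    clone_a, clone_b = tumor_clones(panel, shared_expression=True, high_depth_profile=True)
    cfg = SimConfig(
        n_cells_per_population={"clone_a": n_per_clone, "clone_b": n_per_clone},
        fragments_per_cell=fragments_per_cell,
        lognormal_sigma=0.0,
        dropout_midpoint_fpkm=0.0,  # dropout disabled
        master_seed=seed,
    )
    return panel, [clone_a, clone_b], cfg


def mixed_population_experiment(seed: int = 11, n_tumor: int = 15, n_wbc: int = 10,
                                fragments_per_cell: int = 20_000):
    """Noisy tumor/leukocyte mixture for expression analyses.

    Clone expression profiles are similar but separable; lognormal noise and
    logistic dropout are on at their defaults.
    """
    panel = demo_panel(seed=2017)
    clone_a, clone_b = tumor_clones(panel, shared_expression=False)
    cfg = SimConfig(
        n_cells_per_population={"clone_a": n_tumor, "clone_b": n_tumor, "wbc": n_wbc},
        fragments_per_cell=fragments_per_cell,
        master_seed=seed,
    )
    return panel, [clone_a, clone_b, wbc_population()], cfg


def demo_pipeline_config(experiment: str = "mixed", seed: int = 11):
    """Serialize one of the packaged experiments as a validated PipelineConfig."""
    from .pipeline import PipelineConfig

    builders = {
        "mixed": mixed_population_experiment,
        "two_clone": two_clone_experiment,
        "detection": detection_experiment,
    }
    if experiment not in builders:
        raise ValueError(f"unknown experiment {experiment!r}")
    panel, populations, sim = builders[experiment](seed=seed)
    raw = {
        "seed": seed,
        "panel": {
            "seed": panel.seed,
            "genes": [
                {"id": g.gene_id, "length": g.transcript_length,
                 "marker_role": g.marker_role}
                for g in panel.genes
            ],
            "snps": [
                {"gene": s.gene_id, "position": s.position, "ref": s.ref_base,
                 "alt": s.alt_base}
                for s in panel.snps
            ],
            "deletions": [
                {"gene": d.region.gene_id, "start": d.region.start,
                 "end": d.region.end, "carrier": p.label, "zygosity": d.zygosity}
                for p in populations
                for d in p.deletions
            ],
        },
        "populations": [
            {
                "label": p.label,
                "n_cells": sim.n_cells_per_population.get(p.label, 0),
                "mean_fpkm": {g: float(v) for g, v in p.mean_fpkm.items()},
                "genotype": {f"{g}:{pos}": z for (g, pos), z in p.genotype.items()},
            }
            for p in populations
        ],
        "sim": {
            "read_length": sim.read_length,
            "fragment_length": sim.fragment_length,
            "fragments_per_cell": sim.fragments_per_cell,
            "lognormal_sigma": sim.lognormal_sigma,
            "dropout_midpoint_fpkm": sim.dropout_midpoint_fpkm,
            "dropout_slope": sim.dropout_slope,
            "coverage_mode": sim.coverage_mode,
            "error_rate": sim.error_rate,
        },
    }
    return PipelineConfig.model_validate(raw)


def detection_experiment(seed: int = 11, n_cells: int = 40,
                         fragments_per_cell: int = 20_000,
                         coverage_mode: str = "full_length"):
    """Single-population experiment whose site expression spans the
    detection transition zone, for the coverage-model regression."""
    panel = demo_panel(seed=2017)
    clone_a, _ = tumor_clones(panel, shared_expression=True)
    cfg = SimConfig(
        n_cells_per_population={"clone_a": n_cells},
        fragments_per_cell=fragments_per_cell,
        coverage_mode=coverage_mode,
        master_seed=seed,
    )
    return panel, [clone_a], cfg
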