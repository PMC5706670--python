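"""End-to-end orchestration: config schema, simulation -> quantification ->
classification -> variant profiling -> coverage model -> clustering, plus the
protocol-yield arithmetic.

The YAML config is schema-validated (unknown keys rejected) before any work;
every analysis threshold is echoed into the report. Identical config + seed
gives a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from sklearn.metrics import adjusted_rand_score

from .alignments import build_pileup, pileup_by_position, write_sam
from .clustering import (
    ClusterTree,
    hierarchical_cluster,
    multiscale_bootstrap,
    significant_clusters,
    spearman_distance,
    to_newick,
)
from .coverage import fit_detection_regression
from .expression import (
    ExpressionMatrix,
    MarkerPanelConfig,
    classify_matrix,
    correlation_matrix,
    count_fragments,
    group_correlation_summary,
    pool_bulk_profile,
    spearman,
)
from .reference import (
    DeletionTruth,
    GeneModel,
    PanelConfigError,
    ReferencePanel,
    SNPSite,
    build_reference,
)
from .simulate import (
    CellTruth,
    DeletionCarriage,
    PopulationSpec,
    SimConfig,
    sample_cells,
    simulate_reads,
)
from .variants import (
    VariantMatrix,
    detect_deletion,
    pairwise_variant_distances,
    site_counts,
)

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- protocol yield

@dataclass(frozen=True)
class StageEfficiencies:
    """Per-stage efficiencies of the wet-lab protocol (fractions in [0, 1]):
    magnetic capture, release from the sifter, FACS sort, cDNA synthesis."""

    capture: float
    release: float
    sort: float
    cdna: float

    def __post_init__(self):
        for name in ("capture", "release", "sort", "cdna"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} efficiency {v} outside [0, 1]")


def overall_yield(eff: StageEfficiencies) -> float:
    """Final protocol yield: the product of the four stage efficiencies."""
    return eff.capture * eff.release * eff.sort * eff.cdna


# ------------------------------------------------------------- config schema

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneCfg(_Strict):
    id: str
    length: int
    marker_role: str = "none"


class SnpCfg(_Strict):
    gene: str
    position: int
    ref: str
    alt: str


class DeletionCfg(_Strict):
    gene: str
    start: int
    end: int
    carrier: str
    zygosity: str = "het"


class PanelCfg(_Strict):
    seed: int = 2017
    genes: list[GeneCfg]
    snps: list[SnpCfg] = Field(default_factory=list)
    deletions: list[DeletionCfg] = Field(default_factory=list)


class PopulationCfg(_Strict):
    label: str
    n_cells: int
    mean_fpkm: dict[str, float]
    genotype: dict[str, str] = Field(default_factory=dict)  # "GENE:pos" -> zygosity


class SimCfg(_Strict):
    read_length: int = 75
    fragment_length: int = 200
    fragments_per_cell: int = 20_000
    lognormal_sigma: float = 1.0
    dropout_midpoint_fpkm: float = 8.0
    dropout_slope: float = 1.5
    coverage_mode: str = "full_length"
    error_rate: float = 0.0


class AnalysisCfg(_Strict):
    min_depth: int = 1
    min_alt_reads: int = 1
    call_min_depth: int = 3
    het_band: tuple[float, float] = (0.2, 0.8)
    min_shared_sites: int = 5
    expressed_threshold: float = 1.0
    epithelial_genes: list[str] = Field(default_factory=lambda: ["EPCAM", "KRT7", "KRT8"])
    leukocyte_genes: list[str] = Field(default_factory=lambda: ["CD45"])
    bootstrap_scales: list[float] = Field(
        default_factory=lambda: [round(0.5 + 0.1 * i, 1) for i in range(10)]
    )
    bootstrap_b: int = 1000
    expression_bootstrap_b: int = 200
    alpha: float = 0.05
    bulk_pool_size: int = 10
    min_gap_reads: int = 2
    min_gap_fraction: float = 0.2


class ReportCfg(_Strict):
    write_sam: bool = False


class PipelineConfig(_Strict):
    seed: int = 11
    panel: PanelCfg
    populations: list[PopulationCfg]
    sim: SimCfg = Field(default_factory=SimCfg)
    analysis: AnalysisCfg = Field(default_factory=AnalysisCfg)
    report: ReportCfg = Field(default_factory=ReportCfg)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.model_validate(raw)


def config_to_objects(cfg: PipelineConfig):
    """Materialize the validated config into panel/population/sim objects."""
    genes = [GeneModel(g.id, g.length, g.marker_role) for g in cfg.panel.genes]
    snps = [SNPSite(s.gene, s.position, s.ref, s.alt) for s in cfg.panel.snps]
    deletions = [
        DeletionTruth(d.gene, d.start, d.end, carrier_population=d.carrier)
        for d in cfg.panel.deletions
    ]
    panel = build_reference(genes, snps, deletions, seed=cfg.panel.seed)
    carriage = {
        d.carrier: DeletionCarriage(
            DeletionTruth(d.gene, d.start, d.end, carrier_population=d.carrier),
            d.zygosity,
        )
        for d in cfg.panel.deletions
    }
    populations = []
    for p in cfg.populations:
        genotype = {}
        for key, z in p.genotype.items():
            gene, pos = key.rsplit(":", 1)
            genotype[(gene, int(pos))] = z
        dels = (carriage[p.label],) if p.label in carriage else ()
        populations.append(
            PopulationSpec(label=p.label, mean_fpkm=p.mean_fpkm,
                           genotype=genotype, deletions=dels)
        )
    sim = SimConfig(
        n_cells_per_population={p.label: p.n_cells for p in cfg.populations},
        master_seed=cfg.seed,
        **cfg.sim.model_dump(),
    )
    return panel, populations, sim


# ------------------------------------------------------------ experiment core

@dataclass
class ExperimentData:
    """Everything downstream analyses need, accumulated cell by cell."""

    panel: ReferencePanel
    populations: list[PopulationSpec]
    sim: SimConfig
    cells: list[CellTruth]
    expression: ExpressionMatrix
    variants: VariantMatrix
    deletion_calls: list

    @property
    def truth_labels(self) -> dict[str, str]:
        return {c.cell_id: c.population for c in self.cells}


def simulate_experiment(
    panel: ReferencePanel,
    populations: Sequence[PopulationSpec],
    sim: SimConfig,
    min_depth: int = 1,
    min_alt_reads: int = 1,
    min_gap_reads: int = 2,
    min_gap_fraction: float = 0.2,
    sam_dir=None,
) -> ExperimentData:
    """Simulate all cells and reduce reads to expression + variant matrices.

    Cells are processed one at a time (reads are never all held in memory);
    per cell the reads become fragment counts, per-gene pileups, SNP site
    counts and deletion calls.
    """
    pop_by_label = {p.label: p for p in populations}
    cells = sample_cells(list(populations), sim, panel)
    gene_ids = panel.gene_ids
    sites = panel.snps
    genes_with_sites = sorted({s.gene_id for s in sites})
    n_sites, n_cells = len(sites), len(cells)
    depth = np.zeros((n_sites, n_cells), dtype=np.int64)
    refc = np.zeros((n_sites, n_cells), dtype=np.int64)
    altc = np.zeros((n_sites, n_cells), dtype=np.int64)
    count_cols = {}
    deletion_calls = []
    if sam_dir is not None:
        Path(sam_dir).mkdir(parents=True, exist_ok=True)

    for j, cell in enumerate(cells):
        t0 = time.perf_counter()
        records = simulate_reads(cell, panel, pop_by_label[cell.population], sim)
        if sam_dir is not None:
            with open(Path(sam_dir) / f"{cell.cell_id}.sam", "w") as fh:
                write_sam(records, panel.lengths, fh, cell_id=cell.cell_id)
        counts = count_fragments(records, gene_ids, cell_ids=[cell.cell_id])
        count_cols[cell.cell_id] = counts[cell.cell_id]
        by_gene: dict[str, list] = {}
        for rec in records:
            by_gene.setdefault(rec.gene_id, []).append(rec)
        for gid in genes_with_sites:
            pile = pileup_by_position(build_pileup(by_gene.get(gid, []), gid))
            for i, s in enumerate(sites):
                if s.gene_id != gid:
                    continue
                d, r, a = site_counts(pile, s)
                depth[i, j], refc[i, j], altc[i, j] = d, r, a
        for region in panel.deletions:
            deletion_calls.append(
                detect_deletion(
                    by_gene.get(region.gene_id, []), region,
                    min_gap_reads=min_gap_reads,
                    min_gap_fraction=min_gap_fraction,
                    cell_id=cell.cell_id,
                )
            )
        logger.info("cell %s: %d reads in %.2fs", cell.cell_id, len(records),
                    time.perf_counter() - t0)

    counts_df = pd.DataFrame(count_cols, index=gene_ids).fillna(0).astype(int)
    expr = ExpressionMatrix.from_counts(counts_df, panel.lengths)
    vm = VariantMatrix(
        sites=list(sites), cells=[c.cell_id for c in cells],
        depth=depth, ref_count=refc, alt_count=altc,
        min_depth=min_depth, min_alt_reads=min_alt_reads,
    )
    return ExperimentData(
        panel=panel, populations=list(populations), sim=sim, cells=cells,
        expression=expr, variants=vm, deletion_calls=deletion_calls,
    )


def variant_code_distance_fn(cells: Sequence[str], min_shared_sites: int = 5):
    """Distance function over genotype-code feature matrices for the bootstrap."""

    def fn(codes: np.ndarray) -> np.ndarray:
        return pairwise_variant_distances(codes, cells, min_shared_sites).values

    return fn


def partition_labels(cells: Sequence[str], clusters: Sequence[frozenset]) -> list[int]:
    """Cluster index per cell; cells outside every cluster get singletons."""
    out = []
    nxt = len(clusters)
    for c in cells:
        for k, s in enumerate(clusters):
            if c in s:
                out.append(k)
                break
        else:
            out.append(nxt)
            nxt += 1
    return out


# -------------------------------------------------------------- full pipeline

def run_pipeline(cfg: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Execute the full analysis on a simulated experiment; write report + tables."""
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    an = cfg.analysis

    stage = "simulate"
    try:
        panel, populations, sim = config_to_objects(cfg)
        data = simulate_experiment(
            panel, populations, sim,
            min_depth=an.min_depth, min_alt_reads=an.min_alt_reads,
            min_gap_reads=an.min_gap_reads, min_gap_fraction=an.min_gap_fraction,
            sam_dir=(out / "sam") if cfg.report.write_sam else None,
        )

        stage = "quantify"
        data.expression.counts.to_csv(out / "counts.tsv", sep="\t")
        data.expression.fpkm.to_csv(out / "fpkm.tsv", sep="\t")

        stage = "classify"
        marker_panel = MarkerPanelConfig(
            epithelial_genes=frozenset(an.epithelial_genes),
            leukocyte_genes=frozenset(an.leukocyte_genes),
            expressed_threshold=an.expressed_threshold,
        )
        labels = classify_matrix(data.expression, marker_panel)
        labels.rename_axis("cell_id").to_csv(out / "classification.tsv", sep="\t")
        truth = data.truth_labels
        class_counts: dict[str, dict[str, int]] = {}
        for cell_id, lab in labels.items():
            class_counts.setdefault(truth[cell_id], {}).setdefault(lab, 0)
            class_counts[truth[cell_id]][lab] += 1

        stage = "correlate"
        corr = correlation_matrix(data.expression)
        corr.to_csv(out / "correlation.tsv", sep="\t")
        groups = {c.cell_id: c.population for c in data.cells}
        group_summary = group_correlation_summary(corr, groups)
        group_summary.to_csv(out / "group_correlations.tsv", sep="\t", index=False)
        bulk_corr = _bulk_correlations(data, an.bulk_pool_size)

        stage = "variant-profile"
        data.variants.long_table(an.call_min_depth, tuple(an.het_band)).to_csv(
            out / "variant_long.tsv", sep="\t", index=False
        )
        data.variants.site_summary().to_csv(out / "site_summary.tsv", sep="\t", index=False)
        del_df = pd.DataFrame(
            [
                {
                    "cell_id": d.cell_id,
                    "gene": d.region.gene_id,
                    "start": d.region.start,
                    "end": d.region.end,
                    "spanning_reads": d.spanning_reads,
                    "gap_reads": d.gap_reads,
                    "called": d.called,
                    "note": d.note,
                }
                for d in data.deletion_calls
            ]
        )
        del_df.to_csv(out / "deletion_calls.tsv", sep="\t", index=False)

        stage = "coverage-model"
        regression = fit_detection_regression(data.variants, data.expression)
        regression.site_table.to_csv(out / "detection_sites.tsv", sep="\t", index=False)

        stage = "cluster-expression"
        expr_tree = multiscale_bootstrap(
            data.expression.log_fpkm(),
            spearman_distance,
            scales=an.bootstrap_scales,
            B=an.expression_bootstrap_b,
            seed=cfg.seed + 101,
        )
        (out / "expression_tree.nwk").write_text(to_newick(expr_tree) + "\n")
        expr_tree.node_table().to_csv(out / "expression_nodes.tsv", sep="\t", index=False)
        expr_sig = significant_clusters(expr_tree, an.alpha)

        stage = "cluster-variants"
        codes = data.variants.genotype_codes(an.call_min_depth, tuple(an.het_band))
        var_tree = multiscale_bootstrap(
            pd.DataFrame(codes, columns=data.variants.cells),
            variant_code_distance_fn(data.variants.cells, an.min_shared_sites),
            scales=an.bootstrap_scales,
            B=an.bootstrap_b,
            seed=cfg.seed + 202,
        )
        (out / "variant_tree.nwk").write_text(to_newick(var_tree) + "\n")
        var_tree.node_table().to_csv(out / "variant_nodes.tsv", sep="\t", index=False)
        var_sig = significant_clusters(var_tree, an.alpha)

        stage = "report"
        cell_ids = [c.cell_id for c in data.cells]
        truth_vec = [truth[c] for c in cell_ids]
        report = {
            "version": _version(),
            "seed": cfg.seed,
            "n_cells": {p.label: sim.n_cells_per_population.get(p.label, 0)
                        for p in populations},
            "thresholds": an.model_dump(),
            "classification_counts": class_counts,
            "group_correlations": group_summary.to_dict(orient="records"),
            "bulk_correlations": bulk_corr,
            "detection_regression": regression.summary(),
            "expression_clusters": {
                "significant": sorted(sorted(s) for s in expr_sig),
                "ari_vs_truth": adjusted_rand_score(
                    truth_vec, partition_labels(cell_ids, expr_sig)
                ),
            },
            "variant_clusters": {
                "significant": sorted(sorted(s) for s in var_sig),
                "ari_vs_truth": adjusted_rand_score(
                    truth_vec, partition_labels(cell_ids, var_sig)
                ),
            },
            "deletion_calls": {
                "n_called": int(del_df["called"].sum()) if len(del_df) else 0,
                "by_population": {
                    pop: int(
                        del_df[del_df.cell_id.map(truth) == pop]["called"].sum()
                    )
                    for pop in sim.n_cells_per_population
                }
                if len(del_df)
                else {},
            },
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _bulk_correlations(data: ExperimentData, pool_size: int) -> dict:
    """Pooled-bulk profiles per population and their pairwise correlations."""
    out: dict[str, float | None] = {}
    profiles = {}
    for pop in data.populations:
        ids = [c.cell_id for c in data.cells if c.population == pop.label][:pool_size]
        if len(ids) >= 2:
            bulk = pool_bulk_profile(data.expression.counts, ids, data.panel.lengths,
                                     label=pop.label)
            profiles[pop.label] = np.log2(bulk[pop.label] + 1.0)
    labels = sorted(profiles)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            out[f"{a}|{b}"] = spearman(profiles[a], profiles[b])
    return out


def _version() -> str:
    from . import __version__

    return __version__
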