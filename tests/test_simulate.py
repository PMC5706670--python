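"""Generator contracts: census, noise limits, fragment sampling, variants in reads."""

import json

import numpy as np
import pytest

from ctcseq.reference import DeletionTruth, GeneModel, PanelConfigError, SNPSite, build_reference
from ctcseq.simulate import (
    DeletionCarriage,
    PopulationSpec,
    SimConfig,
    dropout_probability,
    emit_dataset,
    sample_cells,
    simulate_reads,
)


def _panel(genes=None, snps=(), deletions=()):
    genes = genes or [GeneModel("G1", 1000), GeneModel("G2", 1000)]
    return build_reference(genes, list(snps), list(deletions), seed=9)


def _cfg(**kw):
    base = dict(
        n_cells_per_population={"A": 1},
        fragments_per_cell=1000,
        lognormal_sigma=0.0,
        dropout_midpoint_fpkm=0.0,
        master_seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


def test_exact_census_per_population():
    panel = _panel()
    pops = [
        PopulationSpec("A", {"G1": 10.0, "G2": 5.0}),
        PopulationSpec("B", {"G1": 10.0, "G2": 5.0}),
    ]
    cells = sample_cells(pops, _cfg(n_cells_per_population={"A": 20, "B": 20}), panel)
    labels = [c.population for c in cells]
    assert labels.count("A") == 20 and labels.count("B") == 20


def test_noise_free_limit_reproduces_means_exactly():
    panel = _panel()
    pops = [PopulationSpec("A", {"G1": 12.5, "G2": 3.0})]
    cells = sample_cells(pops, _cfg(n_cells_per_population={"A": 5}), panel)
    for c in cells:
        assert c.relative_abundance == {"G1": 12.5, "G2": 3.0}


@pytest.mark.parametrize("slope", [0.5, 1.5, 4.0])
def test_dropout_probability_is_half_at_midpoint(slope):
    assert dropout_probability(8.0, 8.0, slope) == pytest.approx(0.5)


def test_dropout_probability_limits():
    assert dropout_probability(0.0, 8.0, 1.5) == 1.0   # unexpressed gene
    assert dropout_probability(5.0, 0.0, 1.5) == 0.0   # dropout disabled


def test_negative_cell_count_rejected():
    with pytest.raises(PanelConfigError):
        _cfg(n_cells_per_population={"A": -1})


def test_fragment_counts_proportional_to_abundance_times_length():
    """Two equal-length genes at 3:1 abundance: fragment split is binomial."""
    panel = _panel()
    pop = PopulationSpec("A", {"G1": 3.0, "G2": 1.0})
    cfg = _cfg(fragments_per_cell=100_000)
    cell = sample_cells([pop], cfg, panel)[0]
    recs = simulate_reads(cell, panel, pop, cfg)
    frags = {r.read_id for r in recs if r.gene_id == "G1"}
    n1 = len(frags)
    n = 100_000
    p = 0.75
    assert abs(n1 - n * p) < 3 * np.sqrt(n * p * (1 - p))


def test_zero_abundance_gene_emits_no_reads():
    panel = _panel()
    pop = PopulationSpec("A", {"G1": 5.0, "G2": 0.0})
    cfg = _cfg()
    cell = sample_cells([pop], cfg, panel)[0]
    recs = simulate_reads(cell, panel, pop, cfg)
    assert all(r.gene_id == "G1" for r in recs)


def test_hom_alt_snp_substituted_in_every_covering_read():
    site = SNPSite("G1", 500, "A", "G")
    panel = _panel(snps=[site])
    pop = PopulationSpec("A", {"G1": 5.0, "G2": 1.0}, genotype={site.key: "hom_alt"})
    cfg = _cfg(fragments_per_cell=5000)
    cell = sample_cells([pop], cfg, panel)[0]
    bases = []
    for r in simulate_reads(cell, panel, pop, cfg):
        if r.gene_id == "G1" and r.start <= 500 < r.end:
            bases.append(r.seq[500 - r.start])
    assert bases and set(bases) == {"G"}


def test_het_snp_allele_balance_within_binomial_error():
    site = SNPSite("G1", 500, "A", "G")
    panel = _panel(snps=[site])
    pop = PopulationSpec("A", {"G1": 5.0, "G2": 1.0}, genotype={site.key: "het"})
    cfg = _cfg(fragments_per_cell=20_000)
    cell = sample_cells([pop], cfg, panel)[0]
    alt_frags, cover_frags = set(), set()
    for r in simulate_reads(cell, panel, pop, cfg):
        if r.gene_id == "G1" and r.start <= 500 < r.end:
            cover_frags.add(r.read_id)
            if r.seq[500 - r.start] == "G":
                alt_frags.add(r.read_id)
    n = len(cover_frags)
    assert n >= 200
    assert abs(len(alt_frags) - 0.5 * n) < 4 * np.sqrt(n * 0.25)


def test_deletion_carriers_emit_gapped_reads_and_noncarriers_none():
    region = DeletionTruth("G1", 400, 415, carrier_population="A")
    panel = _panel(deletions=[region])
    carrier = PopulationSpec(
        "A", {"G1": 5.0, "G2": 1.0}, deletions=(DeletionCarriage(region, "hom_alt"),)
    )
    control = PopulationSpec("B", {"G1": 5.0, "G2": 1.0})
    cfg = _cfg(n_cells_per_population={"A": 1, "B": 1}, fragments_per_cell=5000)
    ca, cb = sample_cells([carrier, control], cfg, panel)

    def gaps(cell, pop):
        return [
            r for r in simulate_reads(cell, panel, pop, cfg)
            if any(op == "D" for op, _ in r.segments)
        ]

    carrier_gaps = gaps(ca, carrier)
    assert carrier_gaps
    for r in carrier_gaps:
        assert r.deletion_intervals() == [(400, 415)]
    assert gaps(cb, control) == []


def test_reads_deterministic_given_cell_seed():
    panel = _panel()
    pop = PopulationSpec("A", {"G1": 2.0, "G2": 1.0})
    cfg = _cfg()
    cell = sample_cells([pop], cfg, panel)[0]
    assert simulate_reads(cell, panel, pop, cfg) == simulate_reads(cell, panel, pop, cfg)


def test_gene_shorter_than_fragment_excluded_with_warning(caplog):
    panel = build_reference([GeneModel("SHORT", 210), GeneModel("G2", 1000)], seed=2)
    pop = PopulationSpec("A", {"SHORT": 50.0, "G2": 1.0})
    cfg = _cfg(fragment_length=300)
    cell = sample_cells([pop], cfg, panel)[0]
    with caplog.at_level("WARNING"):
        recs = simulate_reads(cell, panel, pop, cfg)
    assert all(r.gene_id == "G2" for r in recs)
    assert any("SHORT" in m for m in caplog.messages)


def test_emit_dataset_manifest_and_determinism(tmp_path):
    panel = _panel()
    pops = [PopulationSpec("A", {"G1": 5.0, "G2": 1.0})]
    cfg = _cfg(n_cells_per_population={"A": 2}, fragments_per_cell=200)
    cells = sample_cells(pops, cfg, panel)
    m1 = emit_dataset(cells, panel, pops, cfg, tmp_path / "d1")
    m2 = emit_dataset(cells, panel, pops, cfg, tmp_path / "d2")
    assert sorted(m1["files"]) == sorted(
        ["reference.fasta", "gene_models.tsv", "snp_sites.tsv", "deletions.tsv",
         "cell_truth.tsv", "A_000.sam", "A_001.sam"]
    )
    assert m1["files"] == m2["files"]  # identical sha256 per file


def test_emit_dataset_zero_cells(tmp_path):
    panel = _panel()
    pops = [PopulationSpec("A", {"G1": 5.0, "G2": 1.0})]
    cfg = _cfg(n_cells_per_population={"A": 0})
    manifest = emit_dataset([], panel, pops, cfg, tmp_path / "d0")
    assert manifest["cells"] == []
    assert (tmp_path / "d0" / "manifest.json").exists()
    json.loads((tmp_path / "d0" / "manifest.json").read_text())
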