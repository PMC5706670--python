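# ctcseq

Joint phenotype + genotype analysis of full-length single-cell mRNA-seq of
rare cells, exercised end-to-end on a simulated circulating-tumor-cell (CTC)
spike-in experiment.

## The problem

Full-length single-cell mRNA-seq chemistries spread reads across entire
transcripts rather than piling them at the 3' end. That makes the same
sequencing run usable twice: once for conventional expression phenotyping,
and once for screening known exonic variants (SNPs and exon deletions) in
whatever genes each cell happens to express. For rare cells — CTCs enriched
out of whole blood, where no material is left for a separate DNA library —
this is the only practical route to simultaneous genotype + phenotype.

`ctcseq` implements that analysis chain as a tested library, together with a
synthetic-data generator that simulates the mixed population such an
experiment interrogates: two tumor clones that share an epithelial expression
phenotype but differ at clone-discriminating SNP sites (one clone also
carrying a 15 bp EGFR-like exon deletion), plus a leukocyte background.
Every stage is exercisable at desk scale without downloads.

## What it computes

* **Expression** — fragment counts per gene per cell and
  `FPKM[g,c] = 10^9 · n[g,c] / (L_g · N_c)` (fragments per kilobase of exon
  per million mapped fragments); pairwise Spearman correlation of
  log2(FPKM+1) profiles; cell classification by the 4-gene CTC marker panel
  (EpCAM/KRT7/KRT8 epithelial vs CD45 leukocyte).
* **Variants** — ref/alt base counts at listed SNP sites from read pileups
  (CIGAR M/D/S dialect, deletion-aware), threshold genotype calls
  (VAF bands), exon-deletion calls from gapped reads, and a cell–cell
  variant distance (weighted genotype discordance; het↔hom = 0.5,
  ref↔non-ref = 1).
* **Coverage model** — the detection heuristic: per-site detection fraction
  (cells with ≥1 read at the site) regressed on log2 mean FPKM by OLS,
  reporting slope, r², and the FPKM at the 50%-detection crossing
  `FPKM50 = 2^((0.5 − b0)/b1)`; plus a closed-form uniform-coverage
  probability `P = 1 − (1 − q)^N` used as the analytic oracle.
* **Clustering** — average-linkage hierarchical clustering on either
  distance, with multiscale-bootstrap support: features (genes or sites) are
  resampled at scales r ∈ {0.5,…,1.4}, BP_r(node) is the fraction of
  replicate trees containing the node's exact leaf set, and
  `probit(1 − BP_r) = v·σ + c/σ` (σ = √(1/r)) is fit by weighted least
  squares to give the approximately-unbiased support
  `AU = 100·(1 − Φ(v − c))`; AU ≥ 95 is read as p < 0.05.
* **Protocol yield** — the product of stage efficiencies
  (capture × release × sort × cDNA).

## Worked example

The numbered drivers under `analysis/` run the packaged study conditions and
write tables under `results/`. For example:

```
$ python analysis/06_protocol_yield.py
  capture (magnetic sifter)    92%
  release (elution)            89%
  FACS sort (semi-purity)      50%
  cDNA synthesis               51%
  overall yield                20.9%  (~20%)
```

```
$ python analysis/05_clustering_heterogeneity.py
expression clustering (mixed population): 2 significant clusters (AU >= 95), sizes [10, 30], ARI vs truth = 0.47
variant clustering (two-clone mixture): 2 significant clusters (AU >= 95), sizes [20, 20], ARI vs truth = 1.00
  AU for the clone_a node: 100
  AU for the clone_b node: 100
```

Expression clustering separates phenotypes (leukocytes vs the 30 tumor
cells); variant clustering resolves what expression cannot — the two tumor
clones — recovering the configured 1:1 mix exactly, each clone node with
AU = 100. `analysis/02_expression_profiles.py` prints the correlation
structure (within-population single cells ≈ 0.66–0.74, between tumor clones
≈ 0.55, pooled-bulk split halves ≈ 0.94), and
`analysis/04_snp_detection_model.py` fits the detection regression
(r² = 0.90 on the packaged gradient; paired 3'−5' detection difference
+0.025 with sign-test p = 2×10⁻⁴ in 3'-biased mode, −0.001 and p = 1 in
full-length mode).

A `ctcseq` CLI wraps the same stages for file-level use
(`simulate`, `quantify`, `variants`, `coverage-model`, `cluster`, `yield`,
`run-all`, `demo-config`); see `ctcseq --help`.

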