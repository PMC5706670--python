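# Methods

This note documents the models, parameters, and numerical choices behind
`ctcseq`: what the simulator generates, how each analysis stage is defined,
and what passing the test suite does and does not establish about real data.

## 1. Synthetic experiment

### Reference transcriptome

The reference is transcript-space: each gene is one contiguous
single-isoform sequence, so every position is exonic. Splice structure is
deliberately out of scope — the analyses operate on exonic positions of
expressed isoforms, and nothing downstream would change with introns
present. Sequences are uniform random over {A,C,G,T}; the base at every
catalogued SNP position is forced to the site's reference base so the
emitted FASTA and the truth tables can never disagree. Coordinates are
0-based half-open everywhere internally; SAM output is 1-based per the
standard.

### Populations and cells

A population carries a mean expression profile on the FPKM scale, a
genotype (zygosity per catalogued SNP site), and optionally one deletion
per gene with its own zygosity. A cell realizes the profile as

    abundance_g = mean_g · exp(ε_g) · keep_g,   ε_g ~ N(0, σ²),
    keep_g ~ Bernoulli(1 − p_drop(mean_g)),
    p_drop(m) = 1 / (1 + (m / m₀)^s),

i.e. multiplicative lognormal noise plus logistic-in-log-expression dropout,
the minimal mechanism reproducing the bimodal presence/absence pattern of
single-cell RNA-seq. Defaults: σ = 1.0 (chosen so that within-population
single-cell Spearman correlations land in the 0.6–0.75 range reported for
single-cell vs bulk comparisons of this kind), dropout midpoint m₀ = 8 FPKM
and slope s = 1.5 (a transition spanning roughly 2–30 FPKM; without dropout
the detection-vs-expression relationship would saturate at 1 and carry no
information). Setting m₀ ≤ 0 disables dropout. Cell counts per population
are exact, not multinomial, so mixing-ratio recovery tests are sharp. If a
dropout draw silences every gene in a cell, the draw is repeated from the
same stream (a cell must transcribe something); with the packaged panels
this is a measure-zero event.

### Reads

Each cell emits a fixed number of fragments (default 200,000 at full
experiment scale; the packaged desk-scale experiments use 50,000 for the
deep noiseless mixture and 20,000 for the noisy ones — sizes chosen so every
catalogue site is covered in every cell in the former, and so the detection
transition is visible in the latter). A fragment picks its gene with
probability ∝ abundance × transcript length (FPKM-scale abundance times
length is fragment mass), draws a parental allele fairly, and places its
start uniformly over the allele transcript (`full_length` mode). Two 75 bp
mates at the fragment ends are emitted born-aligned. All heterozygous
variants of a population are phased onto allele 1: a fragment's single
allele draw jointly decides its het SNP bases and whether it carries a het
deletion. A read crossing a deletion junction skips the whole interval,
producing an M/D/M CIGAR; reads are error-free by default (an optional
uniform substitution rate exists but no error model is claimed).
`three_prime_biased` mode draws fragment starts from a truncated
exponential toward the 3' end (rate 3/L) and exists only as the contrast to
the full-length hypothesis.

What the generator does **not** emulate: sequencing errors and quality
scores, alignment ambiguity, multi-isoform splicing, UMIs and duplication,
batch effects, allele-specific expression, RNA editing. Tests passing here
therefore demonstrate the correctness of the analysis chain under its own
model assumptions — not robustness to the full noise structure of real
reads.

## 2. Alignments and pileups

The SAM dialect is minimal and strict: @SQ/@RG headers, FLAG used for mate
pairing only, CIGAR restricted to M/D/S. Anything else is a parse error —
wider SAM would smuggle in semantics (splices, insertions) the counters do
not implement. Soft clips consume query only and never count. Pileups tally
base counts per position from M segments and deletion-spanning reads
separately from D segments; deletion spans contribute zero depth. Mates
overlapping the same position count twice (no mate-aware deduplication):
the simplest consistent rule, matching read-level counting tools, and
irrelevant to the detection statistic, which thresholds at depth ≥ 1. No
base- or mapping-quality filtering is applied (simulated reads carry none).

## 3. Expression

FPKM is the unit of record: `10^9 · count / (length · total)`. Correlations
are Spearman on log2(FPKM+1) over all genes; the transform is monotone so
Spearman is unaffected, but it pins the scale reused by the expression
clustering distance (1 − ρ). Zero-variance profiles yield NaN correlations,
which propagate as flagged missing values. Bulk profiles are pooled
fragments of k cells re-normalized as one column.

The marker rule quantifies "high epithelial, no CD45": a cell is epithelial
iff ≥ 2 of {EpCAM, KRT7, KRT8} are at ≥ 1 FPKM **and** CD45 < 1 FPKM;
leukocyte iff CD45 ≥ 1 and all epithelial markers < 1; otherwise atypical.
The 2-of-3 guard tolerates single-marker dropout; the two-sided structure
means a dropout-afflicted cell degrades to "atypical" and can never be
cross-labeled. Thresholds are configuration, not biology.

## 4. Variants

Only catalogued sites are screened (no de novo discovery): depth, ref and
alt counts per site per cell; third-allele reads count toward depth but
toward neither allele. "Covered" means depth ≥ 1 — the weakest reading of
"has coverage" and the one the detection regression presumes; "mutant
observed" means ≥ 1 alt read; both statistics are exported since either
reading of "observed" may be wanted.

Genotype calls are threshold-based (no likelihoods): uncovered below
depth 3, otherwise by VAF with the het band [0.2, 0.8] inclusive, hom-alt
above, ref below. These are conventional hard-filter defaults.

A deletion is called in a cell when ≥ 2 spanning reads carry a gap
overlapping ≥ 50% of the candidate interval and the gap fraction among
spanning reads is ≥ 0.2 — loose enough for a heterozygous deletion
(expected gap fraction ≈ 0.5 diluted by reads not crossing the junction),
strict enough that error-free non-carriers can never be called.

The variant distance between two cells is the mean weighted genotype
discordance over sites covered in both (missing if < 5 shared): het↔hom
counts 0.5, ref↔anything-nonref counts 1 — allele-count distance on the
0/1/2 scale with the ref↔het step kept at 1 to separate clones sharply from
reference-like profiles.

## 5. Clustering and AU support

Agglomeration is average-linkage (Lance–Williams), implemented in-package
because the merge sequence must expose exact leaf sets per node and break
distance ties deterministically (lowest active-pair position in creation
order). scipy's implementation serves as an independent oracle in the
tests, never as the implementation. Missing pairwise distances are imputed
as the matrix maximum and counted on the tree.

Cluster support is multiscale bootstrap over **features** (genes or SNP
sites; cells are never resampled): at scale r, features are resampled with
replacement to round(r·f), the cells re-clustered, and BP_r(node) is the
fraction of B replicates whose tree contains the node's exact leaf set.
The scale curve converts to an approximately-unbiased probability by
weighted least squares on the probit scale,

    probit(1 − BP_r) ≈ v·σ + c/σ,  σ = √(1/r),
    AU = 100 · (1 − Φ(v − c)),

with binomial delta-method weights B·φ(z)²/(BP(1−BP)). Numerical choice
that matters: BP values of exactly 0 or 1 have unbounded probits, so only
scales with 0 < BP < 1 enter the fit, and the two-parameter model demands
at least three informative scales. Nodes degenerate at (almost) every scale
are decided by mean BP — ceiling ⇒ AU = 100, floor ⇒ AU = 0. This mirrors
the standard implementation of the method and avoids a failure mode where
a node recovered in ~100% of replicates would otherwise receive a
meaningless two-point extrapolation. AU is not monotone in node height and
no such property is asserted. Significant clusters are the maximal
non-root nodes with AU ≥ 100·(1 − α), α = 0.05 by default. B defaults to
1000 per scale (warning below 100); scales default to 0.5–1.4 in steps of
0.1. Trees export as Newick with merge-height branch lengths and AU as
internal node labels.

## 6. Detection heuristic

Per site, detection fraction = share of cells with ≥ 1 read at the site.
The regression of record is **ordinary least squares** of that fraction on
log2 of the gene's mean FPKM across all cells (zeros included in the mean;
sites on one gene share an x but remain separate points). A bounded-response
logistic fit is available as a diagnostic only. The OLS line yields
FPKM50 = 2^((0.5 − intercept)/slope), flagged undefined when the slope is
not positive. Note that FPKM is a relative unit: on a 40-gene panel the
absolute FPKM scale (and hence FPKM50) is inflated by ~3 orders of
magnitude relative to a transcriptome-wide library, so only the linearity
and the existence of a 50% crossing are comparable across settings, not the
crossing's absolute value. The analytic uniform-coverage probability
`1 − (1 − q)^N`, q = (covering start positions)/(T − L + 1), is the oracle
the simulator's full-length mode is validated against.

## 7. Pipeline and protocol yield

The YAML config is pydantic-validated with unknown keys rejected; every
threshold is echoed into `report.json`, and identical config + seed gives a
byte-identical report. All randomness descends from one master seed through
per-cell spawned seeds (cells are simulated independently and reduced one
at a time, so memory stays flat). The protocol-yield operation is plain
arithmetic — the product of capture, release, sort, and cDNA-synthesis
efficiencies, each validated to [0, 1] — provided with the packaged stage
values 0.92 × 0.89 × 0.50 × 0.51 ≈ 0.209 as the worked example.

## 8. Known limitations

* The simulator's dropout is gene-level logistic in mean expression;
  real dropout also depends on transcript length, GC, and capture
  chemistry.
* Genotype calling is threshold-based; at depth 3–5 the het band
  misassigns calls with binomially non-trivial probability (the packaged
  deep experiment sidesteps this by design).
* The variant distance treats sites as independent and unweighted.
* AU values inherit multiscale-bootstrap assumptions (smooth boundary,
  large-feature asymptotics); with 40–55 features the p < 0.05 reading of
  AU ≥ 95 is approximate.
* FPKM50 is panel-relative (see §6).
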