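# Methods

This note records the models, estimators and numerical choices behind
`gbspanel`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Genotype model

Genotypes are diploid alternate-allele dosages in {0, 1, 2} with −1 for
missing. Upstream GBS callers emit diploid calls against a reference
regardless of the sample's true ploidy, so tetraploid and hexaploid
accessions carry the same coding; heterozygote phase is ignored
(0/1 ≡ 1/0). VCF positions are kept 1-based throughout. Multi-allelic
records are ingested and flagged (`n_alleles`), not dropped at read time:
the filter cascade, not the reader, owns the biallelic rule. Missing INFO
annotations become NaN, never zero. INFO floats are normalised to six
significant digits on read so that hand-written decimal values survive
htslib's float32 storage.

Duplicate (chrom, pos) records keep the first occurrence. This is a simple
position-uniqueness rule; haplotype-aware deduplication of GBS tag variants
is a different (and caller-specific) operation that this package does not
attempt.

## Filter cascade

Order: quality → biallelic → mean depth → call rate → MAF. Defaults:
QUAL ≥ 30, QD ≥ 5, FS ≤ 200, mean depth ≥ 5, call rate ≥ 0.80,
MAF ≥ 0.05.

* Removal conditions are strict inequalities (a site with QUAL exactly 30
  survives), matching the common GATK filter-expression convention.
* "Missing level" phrasing is ambiguous in the field; the package exposes a
  plain **minimum call-rate fraction** (0.80 means ≥ 80% of samples called).
* Sites lacking QD/FS/depth annotations pass that sub-criterion by default
  (GBS VCFs frequently lack FS at some sites); a strict mode fails them
  instead.
* MAF is computed over called alleles only; the minor side is folded
  (alt frequency 0.95 ⇒ MAF 0.05, kept at the default threshold).
* Properties enforced by tests: idempotence, telescoping survivor
  accounting, and monotonicity (raising a threshold never adds survivors).

Note a practical interaction: with a rare group of g samples in a panel of
N, a group-private fixed allele has overall frequency g/N, so the MAF
filter silently removes exactly the markers that discriminate small groups
(g/N < min_maf). Cluster discovery is therefore often better run before
the MAF step; the pipeline runs it after, as the conventional order does,
and the worked example in the README shows the consequence.

## Summaries

Directional substitution classes are kept as the 12 ordered ref→alt pairs;
transitions are exactly {A/G, G/A, C/T, T/C}. Density is
n_snps/(length/10⁶) against a packaged bread-wheat chromosome table
(IWGSC RefSeq v1.0 names and lengths, overridable per run); any chromosome
missing from the table is a hard error, never a silent skip. Subgenome rows
sum their chromosomes' counts before ratios are computed. Ratios are
computed on unrounded counts and rounded to two decimals only for
presentation; a ratio with zero transversions is reported as "undefined",
never 0 or ∞.

## Ordination, clustering, DAPC

The relationship matrix standardizes each site by its Hardy–Weinberg
dosage standard deviation √(2pq) and averages cross-products over
pairwise-complete sites, so each sample pair uses exactly the sites both
have called. Monomorphic sites are skipped (logged count). PCoA is a plain
symmetric eigen-decomposition; explained variance is the eigenvalue over
the sum of positive eigenvalues, and each axis's sign is fixed so its
largest-magnitude loading is positive (reproducible output).

Cluster finding runs multi-restart k-means (20 restarts, 300 iterations,
seed 42 by default, all configurable) for k = 1..k_max and scores each k by
BIC(k) = n·ln(WSS_k/n) + k·ln(n). **All** ordination axes are retained by
default, following the adegenet find.clusters convention: in high ambient
dimension a spurious split of a large cluster along noise axes barely
reduces WSS and the k·ln(n) penalty dominates, whereas restricting to a
few axes makes such splits look profitable and the BIC curve decrease
indefinitely. An explicit `k_override` supports elbow-style manual choice.

DAPC reduces mean-imputed dosages by PCA to `n_pcs` axes (default 30) and
fits an LDA on the scores; at most k−1 discriminants are kept and a
stratified cross-validation routine reports held-out accuracy across
candidate `n_pcs`. Missing genotypes are mean-imputed **for ordination and
DAPC only** — never for AMOVA or the chi-square tests, which handle
missingness by pairwise-complete distances and called-allele counts
respectively. A cluster with a single member makes the within-scatter
singular and is rejected with advice to merge.

Neighbor joining is the standard agglomeration on a symmetric distance
matrix (default distance: 1 − proportion of shared alleles over
pairwise-complete sites; Euclidean on dosages available). A negative
branch length at a join is clamped to zero with the deficit transferred to
the sister branch, preserving the joined pair's distance; the final three
nodes form a trifurcating root with three-point branch lengths. Branch
lengths are written with 17 significant digits so additive matrices
round-trip exactly.

## AMOVA and PhiPT

Two-level distance AMOVA treating each sample as an individual (the
GenAlEx-style PhiPT, an FST analogue that ignores within-individual
variation — appropriate for dosage-coded polyploid panels). Squared
Euclidean distances over dosages are rescaled per pair by
(total sites / pairwise-complete sites) to correct for missingness.

SS_total = Σ_{i<j} d²ij/N; SS_within sums within-group pair terms divided
by group size; MS = SS/df with df_among = k−1, df_within = N−k;
n0 = (N − Σn_g²/N)/(k−1); σ²_within = MS_within;
σ²_among = (MS_among − MS_within)/n0, clamped at zero for reporting;
PhiPT = σ²_A/(σ²_A + σ²_W).

The permutation test (default 999 permutations, seed 42) compares the
**unclamped** statistic between observed and permuted labelings: clamping
would collapse every under-dispersed labeling onto zero and pile null
p-values at 1. The reported p uses the (hits+1)/(n_perm+1) correction; its
null uniformity is verified by a KS test in the suite. Pairwise PhiPT runs
the same estimator restricted to each pair of groups. Nucleotide diversity
uses the without-replacement estimator π = 2j(m−j)/(m(m−1)) per site
(m called alleles, j alternate), averaged over sites with m ≥ 2.

## Diagnostic-SNP hierarchy

A discrimination tree is a parent-first list of nodes; each node contrasts
two disjoint taxon-label sets and its sample scope is their union, nested
inside the parent's scope. At a node, every SNP is scored by Pearson's
chi-square (no continuity correction) on the 2×2 table of allele
{ref, alt} × contrast side, built from called alleles only; a zero marginal
yields statistic 0, p = 1. Allele-count granularity (2N) is the default —
it maximises power for the fixed-difference signals diagnostic panels seek
— with a genotype-count (3×2) option.

The default correction is Bonferroni within each node at
α = 0.05 (per-node family-wise control; none and Benjamini–Hochberg
available). Tables failing Cochran's adequacy rule (any expected count
below 5) are flagged `low_expected` but not removed: with very small
contrast sides (≈6 samples) the asymptotic chi-square tail can understate
the exact binomial tail by orders of magnitude, so rare flagged false
positives can survive Bonferroni — the suite verifies that *unflagged*
retained markers are clean under a global null, and users of small groups
should treat flagged markers as provisional.

Each node panel records per-chromosome counts and is verified by a PCoA
restricted to the panel's SNPs and the node's sample scope, reporting the
first two components' explained variance and the silhouette of the
contrast sides on those components. The common/durum wheat tree (species
at the root; sphaerococcum, carthlicum/dicoccon, spelta, turgidum,
aestivum/compactum and durum vs polonicum/turanicum peel-offs) ships as
packaged YAML.

## Synthetic-data generator

The generator emulates a wheat-genebank GBS panel and carries its full
truth:

* **Defaults:** 283 accessions in six groups of sizes
  182/61/12/9/13/6 carrying subgenome sets ABD/AB/A/AB/AG/A; 14,188 sites
  allocated A:B:D = 10,126:3,721:341 by multinomial draw; directional
  class weights shaped like wheat panels (C/T and G/A dominant) with the
  transition share set by a Ts/Tv target of 1.9; alternate-allele
  frequencies uniform on [0.05, 0.5] (no empirical spectrum is available
  for these taxa; the uniform choice is flagged here deliberately); 10%
  i.i.d. missingness; 340 planted diagnostic sites per one-vs-rest
  contrast with a full (δ = 1) frequency differential — 340 is the
  reported per-node diagnostic-panel scale for real wheat GBS data
  (≈2,700 markers over 8 nodes).
* Samples lacking a subgenome are **reference-fixed** at that subgenome's
  sites (non-amplifying loci), a config switch yields missing calls
  instead. G-genome sites default to zero (no reference), so A-only group
  pairs are separated only by planted differentials — the harder case.
* A single seeded generator is consumed in a fixed documented order
  (site allocation → classes → frequencies → diagnostic planting →
  genotypes → missingness → annotations), so identical configs and seeds
  are bit-identical and truth never desynchronises from data.
* QUAL/QD/FS/depth annotations are drawn from benign distributions with a
  configurable fraction of deliberately failing sites, bookkept in truth,
  giving the filter cascade known expected survivors.

**What it does not emulate** — and hence what passing tests do not show
about real data: linkage disequilibrium and recombination maps, coalescent
ancestry, genome-wide background divergence between groups (non-diagnostic
sites share frequencies across groups by construction, so realistic PhiPT
magnitudes like 0.67 are out of reach of the default panel), sequencing
error, and depth-dependent genotype uncertainty.

## Problem sizes used in the suite

The recovery suite runs one 300-sample × 15,000-site panel (six groups in
study proportions, δ = 1) for cluster-number selection, DAPC
cross-validation and hierarchy recovery, plus a same-shape null panel
(identical subgenomes, nothing planted) for false-positive control; the
permutation-calibration suite uses 200 random labelings of a homogeneous
40-sample panel at 199 permutations each. Oracle-equivalence checks use
panels of ≤ 8 samples against brute-force definitional sums, random
additive trees of ≤ 8 taxa, and 100 random 2×2 tables. These sizes give
each check comfortable statistical resolution while keeping the default
suite quick to run.

## Known limitations

* PhiPT here is strictly two-level; hierarchical (≥3-level) AMOVA is out
  of scope.
* The chi-square tests are asymptotic; with contrast sides of ~6 samples
  their p-values are anti-conservative on sparse tables (see the
  `low_expected` flag above).
* The NJ tree is a grouping check, not phylogenetic inference: no
  substitution model, no support values.
* Chromosome-length-based densities require every observed chromosome to
  resolve in the length table; panels on other genomes must supply their
  own table.
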