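# Methods

This note documents the models and numerical choices behind `cx3sig`: what
each stage computes, which parameters matter, what the synthetic-data
generator does and does not emulate, and where the design was genuinely open.

## Study design and populations

All computations assume five sorted CD8+ T-cell populations with biological
replicates: naive (CD62L-high CD45RA+) cells and four CD45RO+ memory
populations defined by CX3CR1 × CD62L surface expression. The two CX3CR1+
populations are treated as carrying the cytotoxic effector program; the
consensus signature is defined as genes high in both of them, intermediate
in the CX3CR1- memory populations, and low in naive cells. Every sample
must carry exactly one of the five population labels; differential testing
requires at least two replicates per population.

## RNA-seq preprocessing

**Size factors.** Median-of-ratios: for sample *j*,
f_j = median over genes (with positive geometric mean across samples) of
count_gj / geomean_g, then rescaled to geometric mean 1. The rescale fixes
the estimator's arbitrary global scale; with it, recomputing factors on an
already-normalized matrix returns exactly ones (idempotence). Scaling one
sample's counts by *c* moves its factor by c^(1-1/n) and every other factor
by c^(-1/n) — the geometric-mean reference shifts too — so factor *ratios*
are exactly scale-equivariant. Genes with a zero count in any sample do not
contribute; if no gene is quantified everywhere the estimator raises rather
than silently switching reference.

**Floor.** Normalized counts below 1 are set to 1. All downstream fold
changes are ratios of floored group means, never model coefficients, so
they are finite and positive; a count of 0 against 500 yields FC 500, not
infinity.

**Present filter.** A gene is present when its mean normalized count
strictly exceeds 10 in at least one population. Microarray data use a fixed
log2 background of 6.7886 instead: probesets below it in *all five* group
means are dropped (a group mean equal to the background keeps the probeset).

**Variable filter.** One-way ANOVA across the five populations, unadjusted
p < 0.05. The test is deliberately the same classical equal-variance ANOVA
used for differential expression; Welch or adjusted-p variants are config
options. No named test or adjustment convention is canonical for this
filter, so both are exposed. The variable set feeds visualization (PCA,
heat maps); the analysis engines below run on the *present* set, which also
keeps the DE stage's p-values interpretable against their nominal level
(a variable-filtered input would be conditioned on p < 0.05).

**PCA.** SVD on centered samples × genes; loadings orthonormal; explained
variances sum to the total variance; each component's sign is fixed so its
largest-magnitude loading is positive.

## Proteome preprocessing

Rows flagged as contaminant, decoy (reverse) or identified only by a site
modification are removed; remaining proteins need at least 3 valid
quantifications in at least one replicate group. Intensities are
log2-transformed. Missing values are then imputed per sample column from a
down-shifted normal: with observed column mean mu and sd sigma (n-1
denominator throughout), missing cells draw from
Normal(mu - 1.8 sigma, (0.3 sigma)^2). This is the standard
missing-not-at-random model for label-free data: values are missing mostly
because they fall below the detection limit, so plausible imputations sit
in the left tail. Whether the reference distribution is per-column or
global is not canonical; per-column is the default (it respects per-run
depth differences) with a global mode in the config.

## Differential expression

Classical one-way ANOVA per gene across the five populations;
Benjamini-Hochberg step-up over all tested genes. Zero-variance genes get
F = 0, p = q = 1 so the tested universe (and hence the BH denominator) is
stable. Contrast fold changes are ratios of floored normalized group means.
"Commonly upregulated" = FC > 2 and q < 0.05 in both CX3CR1+ vs naive
contrasts. Ratio-ratio tables (log10 mean ratios of genes DE in either of
two contrasts) and fold-change rank plots (primary log2FC descending, with
matched secondary values and a count of sign-discordant partners) support
the cross-population and cross-omics concordance views.

## Clustering engines

**MCL.** The correlation graph has an edge wherever Pearson r >= 0.85 (RNA)
or 0.8 (protein); zero-variance genes are excluded with a warning. Markov
clustering adds self-loops of weight 1, column-normalizes, then alternates
expansion (matrix squaring) and inflation (elementwise power 2.2, the
algorithm's customary default, then column renormalization) until the
change falls below 1e-6 or 200 iterations. Entries below 1e-9 are pruned
each iteration, which keeps the matrices sparse and defines the support of
the limit matrix; clusters are the connected components of that support,
singletons are reported as unassigned. Non-convergence returns the current
partition with a warning flag.

**Weighted correlation network analysis.** Unsigned soft-thresholded
adjacency a_ij = |r_ij|^beta (beta = 7 RNA, 18 protein), topological
overlap omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
average-linkage hierarchical clustering of 1 - omega (clipped at 0 against
floating-point undershoot). The dendrogram is cut statically at the height
that maximizes the number of branches of size >= 30, scanning merge heights
(all of them, or 512 quantiles for large trees; ties go to the lowest
height) — a documented simplification of dynamic tree cut. Each module's
eigengene is the first principal component of its row-standardized
expression, unit length, sign-fixed so the mean member correlation is
positive. Module pairs with eigengene dissimilarity (1 - cor) below the
merge threshold (0.3 RNA, 0.5 protein) are merged iteratively, closest pair
first, recomputing eigengenes after every merge.

**Self-organizing map.** 5x5 rectangular grid (25 units), online training
with 20,000 single-gene updates, learning rate decaying linearly
0.05 -> 0.01 and Gaussian neighborhood radius 2 -> 0.5; codebook
initialized from randomly drawn gene profiles (seeded). After training each
gene maps to its best-matching unit, and each unit is summarized by the
first eigenvector of its members' population-mean profiles (sign-fixed to a
positive mean) for heat-map display. The grid topology, schedule and unit
summary are this package's choices; only the unit count and iteration
budget are fixed by convention.

**Effector-cluster selection.** For each cluster, score = (minimum mean
z-score over the two CX3CR1+ populations) - (maximum mean z-score over the
other three). The arg-max cluster is selected; ties break toward the larger
cluster, then the lexicographically first member.

## Consensus signature

Pre-signature = (selected MCL cluster ∩ commonly upregulated) ∪ (selected
network module ∩ commonly upregulated), with per-gene provenance recording
which route(s) contributed. Refinement compares the pooled mean of all
CX3CR1+ samples with the pooled mean of all CX3CR1- samples (pooling the
two subpopulations on each side is this package's reading; a per-pair mode
is configurable): a gene is removed when FC < 1.5 AND |difference| < 50.
The conjunctive reading is the default because the two criteria proxy the
same contrast on different scales (ratio vs absolute) and either alone
would discard genuinely high-contrast genes that are weak on only one
scale; a disjunctive mode is available. Polymorphic MHC class II genes
(a shipped list of classical HLA class II loci, overridable) are removed
last. The proteome refinement uses only the absolute linear-intensity
difference (>= 1e6) plus the blocklist.

An optional config flag additionally subtracts genes significantly
upregulated in both CX3CR1- populations versus naive. It is off by default:
core-signature genes are *expected* to be moderately elevated in CX3CR1-
memory cells (their planted CX3CR1- effect sits exactly at the 2-fold DE
threshold, so the subtraction removes a noise-dependent slice of true
effector genes), and the CX3CR1+ vs CX3CR1- refinement already eliminates
genes without a CX3CR1+ excess.

## Cross-omics matching and GO enrichment

Protein accessions map to gene symbols through an explicit accession->symbol
table; many-to-one cases resolve to the accession with the highest mean
intensity (logged). The signature overlap is refined-RNA ∩ gene-mapped
refined-protein; detected-in-proteome counts signature genes with any
matched, filter-surviving protein row. The expression-class histogram bins
present genes by matched protein log2 intensity into equal-width classes
(unmatched genes form their own class) and histograms log10 RNA expression
per class.

Enrichment is the exact upper-tail hypergeometric test P[X >= k] for k term
members in an n-gene query against a term with K members inside the N-gene
universe, BH-corrected over all tested terms. The universe defaults to the
present-gene set of the relevant omics layer (the background against which
the query was derived); terms without members in the universe are skipped,
not scored. Gene sets are flat GMT collections — no ontology-hierarchy
propagation. The enrichment map keeps terms with q <= 0.025 and joins two
terms when the Jaccard similarity of their universe-restricted memberships
is >= 0.25.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
defaults that are the package's study conditions (used by the test suite
and `scripts/acceptance.py` alike): 5,000 genes, 200 planted effector
genes, 3 co-regulated background modules of 50 genes, 5 replicates per
population.

* Counts are negative binomial with variance mu + 0.1 mu^2 (gamma-Poisson),
  gene base means log-uniform over [5, 5000], and per-sample library-size
  factors log-normal (sdlog 0.3).
* Each planted effector gene carries a per-gene strength e, log-uniform
  over [4, 64], applied identically in both CX3CR1+ populations, against
  multipliers 2 (both CX3CR1- populations) and 1 (naive). The gene-to-gene
  spread mirrors the wide fold-change spectrum of real effector programs
  (granzymes vs adhesion molecules) and is what places signature genes on
  the diagonal of the two CX3CR1+ vs naive ratio-ratio axes; the minimum
  strength 4 keeps every planted gene two-fold above the FC > 2 detection
  threshold in expectation. The effector block also shares a weak
  per-sample log-normal factor (sd 0.25): the program is co-regulated,
  which is precisely why correlation clustering can find it.
* Background modules share a strong per-sample log-normal factor (sd 1.5),
  chosen so the within-module Pearson correlation of normalized counts is
  >= 0.9 (median) after negative-binomial noise at realistic base means.
  Module genes have no population effect.
* Proteins: a random 60% of genes get a row; per-cell log2 intensity is
  20 + log2(RNA level of that sample, floored at 1 count) + N(0, 0.5).
  Coupling to the per-sample RNA level (not the empirical group mean) keeps
  unregulated proteins null across populations — coupling to empirical
  group means would freeze RNA sampling noise into consistent, spurious
  group-level protein effects. Cells drop out with probability logistic in
  minus intensity (midpoint 24, scale 1.5), concentrating missingness at
  low abundance (~20% overall); 2% of rows are flagged contaminants.
* Annotation: terms of size 10-200; planted enriched terms draw 60% of
  members from the signature, background terms draw uniformly.

Everything is a deterministic function of the seed. What the generator does
**not** emulate: isoforms and shared peptides (the accession->gene map is
bijective), batch effects, gene-length bias, count overdispersion
heterogeneity, correlated dropout across samples, and ontology structure
among GO terms. Passing tests therefore demonstrate that the implementation
recovers the structure the method assumes when that structure is present at
realistic noise levels — not that the method is robust to artifacts the
generator omits.

## Numerical conventions and degenerate inputs

Sample standard deviations use the n-1 denominator everywhere. Zero-variance
genes: dropped with a warning by the z-transform, variable filter and
correlation graph; an explicit error in network module detection (a
degenerate correlation matrix would poison TOM); F = 0 / p = 1 in DE.
Missing protein intensities are NaN internally, never 0; a fully missing
sample column is an error for imputation. TSVs are tab-separated UTF-8 with
'.' decimals; gene identifiers are case-sensitive opaque strings matched
exactly. MCL uses pruning threshold 1e-9, convergence tolerance 1e-6,
maximum 200 iterations. Hypergeometric p-values are clamped into (0, 1].
Writers and readers are exact inverses on valid data.

## Reproducibility and problem sizes

Pipelines derive all randomness (imputation draws, SOM sampling) from the
config seed; reruns are byte-identical. The test suite and the reproduction
script exercise the full study at the default 5,000-gene scale (a single
pass takes seconds to a couple of minutes depending on hardware; the
topological-overlap matrix product over ~4,600 present genes dominates) and
use a 1,000-gene version of the same design for the 10-seed label-permuted
null calibration, where only calibration — not power — is at stake.

## Known limitations

* The static dendrogram cut is coarser than dynamic tree cut; on real data
  it typically yields fewer, larger modules, and module *counts* are not
  comparable across cut methods (the effector module's membership, which is
  all the consensus uses, is robust in the planted-structure tests).
* MCL cluster granularity depends on the correlation threshold; genes whose
  profiles correlate below it join no cluster and can only enter the
  signature through the network-module route.
* The consensus path inherits the ANOVA's equal-variance assumption; counts
  are tested on the normalized (not variance-stabilized) scale, which is
  slightly conservative for strongly structured genes and anticonservative
  for very low counts.
* GO enrichment treats terms as flat sets; parent/child double counting is
  not corrected, only visualized via the enrichment map's Jaccard edges.
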