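# Methods

This note documents the models and numerical choices behind `assemblage`:
what each statistic computes, the defaults and why, what the synthetic
generator does and does not emulate, and known limitations.

## Data model

The pipeline's objects are an OTU count table (samples × OTUs, integral
reads, no all-zero OTU columns), a rooted phylogeny with non-negative branch
lengths whose tips are OTU ids, per-sample metadata (coordinates in degrees,
optional season/area labels, any number of numeric environmental columns)
and an OTU taxonomy with a coarse clade label. All interchange formats are
plain text (TSV, newick); writers and readers round-trip exactly.

## Alpha diversity and rarefaction

Rarefaction subsamples each sample to a fixed depth without replacement
(seeded; samples below the depth are dropped with a warning rather than
failing the run, so variable-depth inputs remain usable). On the rarefied
table we report observed richness, Shannon entropy (log base 2 by default —
the index is used comparatively, so the base only sets units; configurable),
bias-corrected Chao1 `S + F1(F1−1)/(2(F2+1))` (finite when doubletons are
absent), Good's coverage `1 − F1/N`, and Faith's PD as the total branch
length of the minimal subtree connecting a sample's tips **to the root**
(the root-inclusive convention; adding a tip can therefore never decrease
PD). Good's coverage is computed on the rarefied table.

## Distance-decay and PERMANOVA

Bray–Curtis is computed on counts (equivalently relative abundances on a
rarefied table; an explicit `normalize` flag exists for unequal depths).
Geographic distances are haversine great-circle distances on a sphere of
radius 6371.0088 km (the mean Earth radius).

Distance-decay is Spearman's rank correlation between the lower triangles
of the community and geographic matrices. Significance uses a Mantel-type
permutation: one matrix's rows and columns are jointly permuted (sample
labels), never individual pairs, because pairwise distances are not
exchangeable. The test is one-tailed for positive decay by default (the
decay hypothesis is directional); two-sided is a flag. P-values are
`(1 + hits)/(1 + n_perm)` with a 1e-12 tolerance when comparing permuted to
observed statistics, so the attainable floor is `1/(n_perm + 1)`; the
default is 999 permutations. For Spearman tests the off-diagonal entries
are ranked once and permutations gather the pre-ranked entries — a label
permutation only rearranges which pair occupies which triangle slot, so the
gathered values are exactly the ranks of the permuted triangle.

Per-clade decay extracts the clade's OTUs and **recomputes** Bray–Curtis
within the subset, renormalizing to within-clade relative abundances by
default (flag to use raw counts); samples with zero clade reads are
dropped with a warning.

PERMANOVA is the one-way sums-of-squares partition of the squared distance
matrix (`SS_total = Σ d²/n`, within-group terms `Σ d²/n_g`), with the
pseudo-F permutation-tested by shuffling group labels. The implementation
is deliberately in-package so the permutation stream is seeded; it is
cross-checked in the tests against a brute-force double-loop oracle and
against an independent library implementation of the statistic.

## The five-process null-model partition

**βMNTD** between samples k and m is the two-way abundance-weighted mean of
nearest-taxon phylogenetic distances,

    βMNTD(k,m) = 0.5·[ Σ_{i∈k} f_ik · min_{j∈m} d_ij + Σ_{j∈m} f_jm · min_{i∈k} d_ij ],

where d is the cophenetic (tip-to-tip path length) matrix and f are
within-sample relative abundances (abundance-weighted by default, the
originating framework's choice; presence/absence weighting by flag). A
taxon shared by both samples is its own nearest neighbour (distance 0), so
identical communities score exactly 0.

**βNTI** standardises the observed βMNTD against a null distribution
generated by shuffling taxa across the phylogeny's tips — a joint
row/column permutation of the cophenetic matrix, holding each sample's
richness and abundances fixed. The default is 999 null draws. Pairs whose
null distribution is degenerate (sd ≤ 1e-12; e.g. on a star phylogeny, or
when two samples share every taxon that carries weight) get an undefined
βNTI: they are excluded from process fractions and counted separately,
never silently assigned to drift.

**RC_bray** compares each pair's observed Bray–Curtis with null pairs
reassembled from the metacommunity (the full input table): a null community
draws the sample's observed richness without replacement with probability
proportional to occupancy frequency, seeds each drawn species with one
read, and distributes the remaining reads multinomially in proportion to
metacommunity relative abundance — so null richness equals observed
richness exactly. The observed dissimilarity's position in the null
distribution is rescaled to [−1, 1], ties counted at half weight
(mid-rank convention):

    RC_bray = 2·[ (#{null < obs} + 0.5·#{null = obs}) / n_null − 0.5 ].

**Classification** per pair: βNTI > 2 → heterogeneous selection;
βNTI < −2 → homogeneous selection; otherwise RC_bray > 0.95 → dispersal
limitation, RC_bray < −0.95 → homogenizing dispersal, else drift. The
stochasticity ratio is the summed fraction of the three stochastic
processes. Boundary values (βNTI = ±2, RC = ±0.95) fall on the
non-selection / drift side, matching the strict inequalities of the rule.
When samples are analysed per season, the metacommunity for RC_bray is the
per-season table; a pooled run uses the pooled table.

**Phylogenetic signal** (the framework's precondition) is tested with a
Mantel correlogram: between-OTU niche distances (Euclidean over z-scored
abundance-weighted environmental optima, all supplied variables) against
cophenetic distances cut into equal-width classes. The class statistic is
the sign-flipped correlation between class membership and niche distance
(positive r = ecological similarity within the class); p-values permute OTU
labels, one-tailed for positive autocorrelation by default, with Holm's
sequential correction across tested classes. Classes with fewer than 10
pairs are reported but not tested.

## Spatial corroboration

PCNM spatial eigenvectors: distances beyond a truncation threshold (default
= the longest minimum-spanning-tree edge, which keeps the neighbour graph
connected) are replaced by 4× the threshold; the matrix is transformed by
`−0.5·W²`, double-centered and eigendecomposed; axes with positive
eigenvalues are kept in principal-coordinate scaling (eigenvector ×
√eigenvalue) with a sign convention (largest-magnitude loading positive)
for reproducibility. Downstream use is sign-invariant. The retained axes
are condensed into a spatial distance matrix (Euclidean over axes) for
Mantel-style analyses; axis selection by constrained ordination is out of
scope, so all positive axes are retained — a documented divergence from
significance-based selection.

Partial Mantel uses the residual method: both triangles are residualised on
the conditioning triangle (after ranking, for Spearman) and the residuals
correlated; permutations relabel the first matrix's samples and
re-residualise before correlating.

VIF screening is iterative and worst-first: recompute all VIFs
(`1/(1−R²)`, intercept included; a perfect fit maps to infinity), drop the
largest while any exceeds the threshold (default 10), repeat. Single-pass
removal can over-remove; worst-first cannot. Ties break by column order. A
zero-variance variable is an error naming the column.

## Co-occurrence networks

OTU filtering keeps taxa with mean within-sample relative abundance
strictly above 0.01% **and** occupancy strictly above 20% of samples (both
cuts strict, so boundary OTUs drop out); filtering always precedes network
construction. Mean (not pooled-count) relative abundance is the default
interpretation, with the pooled variant available.

Edges are Spearman correlations over all remaining OTU pairs. P-values use
the t approximation with mid-ranked ties; for 9 or fewer samples and
tie-free pairs the exact permutation distribution of the statistic is used
(computed once per sample count from all rank permutations — the statistic
is a monotone function of the integer Σd², so exact p reduces to integer
comparisons). Benjamini–Hochberg adjustment is applied over **every**
computed pair before thresholding; an edge requires |ρ| > 0.7 and adjusted
p < 0.01. Constant OTU profiles are skipped with a warning; isolated nodes
are dropped. Construction is fully deterministic, so no seed is taken.

Network-level features: node and edge counts, mean degree 2E/N, global
transitivity (3·triangles / connected triples), average path length and
diameter on the largest connected component, density 2E/(N(N−1)),
modularity Q from deterministic greedy (CNM) agglomeration, and Freeman
degree/betweenness centralizations (normalised so a star scores 1).
Node-level: degree, local clustering, normalised betweenness, and
component-restricted closeness (reachable count / summed distances, so an
isolated dyad's nodes score 1). Edge-free subgraphs report zero path
length, diameter and modularity.

Per-sample subgraphs are induced on the network nodes with non-zero count
in the (filtered) sample. Their topology distance-decay uses Euclidean
distance over the z-scored ten-feature table (the eight above plus node and
edge counts; zero-variance features dropped with a warning, all-constant
features an error) in a Mantel test against geography — the inter-sample
"network structure" distance is not canonical, and this choice is
documented rather than implied.

## Synthetic metacommunities

The generator emulates the structure of a coastal-sediment amplicon survey:
default 58 samples along a 1500 km line transect (alternating seasons, area
labels by patch), J = 12630 reads per sample (a typical rarefaction depth),
a geometric long-tailed regional pool, a temperature-like gradient of
5–25 °C, and a Yule phylogeny rescaled to unit root depth. The default
1000 taxa keep the long tail while staying tractable on a laptop; the demo
configuration used throughout testing is 12 samples × 200 OTUs at J = 5000.
Niche optima evolve by Brownian motion with an early-burst rate shift
(full rate above the clade-depth cut of 0.5, ×0.15 below), so optima are
phylogenetically conserved at the clade level — the regime the correlogram
is designed to detect, and the assumption the βNTI framework requires.
Synthetic clades are the largest subtrees crossing the depth cut.

The five regimes:

* **Heterogeneous selection** — each sample's environment follows the
  gradient; local weights are a narrow Gaussian filter (σ_w = 2 °C) inside
  a hard niche window (the 15% of taxa with optima nearest the local
  environment), times a colonization lottery (each taxon present with
  probability 0.5), plus a thin uniform immigrant rain (0.2% of reads).
  Samples from opposite gradient ends are dominated by different clades.
* **Homogeneous selection** — the same machinery under a constant
  environment at the gradient's high extreme, where clade-conserved optima
  are most clustered. The lottery provides membership turnover between
  samples while selection keeps that turnover phylogenetically narrow.
* **Dispersal limitation** — neutral weights; contiguous patches (default
  4; 3 in the demo) whose local pools drifted independently from the
  regional pool for 30 generations at effective size 500.
* **Homogenizing dispersal** — mass effect: one shared realized community
  of J individuals, each sample replacing a Binomial(J, 0.05) portion with
  fresh draws from the pool. Samples share realized composition *beyond*
  independent sampling — the only way observed dissimilarity can fall
  below the Raup–Crick null's read-sampling noise floor.
* **Drift** — each sample is an independent demographic realization: one
  generation of multinomial drift at effective size 2000, then J reads.
  The drift variance (≈1/2000 per generation) is of the same order as the
  read-sampling variance (1/J), which keeps observed turnover inside the
  null band — distinguishing drift from dispersal limitation, which is
  drift plus isolation strong enough to exceed the null.

Design rationale worth recording: at demo scale (200 tips), βNTI's
magnitude for selection regimes is limited by configuration noise in the
tip-shuffle null — with more than ~20 background (out-of-niche) taxa per
sample the achievable |βNTI| saturates well below 2. The hard niche window
and the small, uniform rain keep each sample's background membership sparse
while the pooled table still spans the whole tree (the null shuffles over
the pooled table's tips). These are properties of the null model's
geometry, not tuning targets.

What the generator does **not** emulate: sequencing error, chimeras,
compositional biases of PCR, taxon-specific read-length effects, or
realistic taxonomic structure. Passing tests demonstrate that the
statistics recover known generating processes under clean conditions; they
do not certify performance on real data with those artefacts.

## Pipeline

`run_pipeline` executes load/simulate → rarefy → alpha → beta/decay →
phylogenetic signal → null models → classification → spatial → network from
a YAML config. A single global seed expands deterministically (via a seed
sequence) into per-stage seeds, so toggling stages does not change the
seeds of the stages that run; identical config + seed yields a
byte-identical `report.json` (floats rounded to 10 decimals in the report;
stage timers go to the log, not the report). Input hashes and all
thresholds are echoed into the report.

## Problem sizes

Tests and the acceptance script run the demo scale (12 × 200, J = 5000,
999 null draws; calibration checks use 200 replicates at 99–199
permutations), the sizes at which the regime-recovery and calibration
properties were validated. The implementation itself is vectorised over
pairs and null draws; 58 samples × a few thousand OTUs is comfortable, with
βNTI memory growing as `n_null × n_samples²` and RC_bray as
`n_samples × n_null × n_taxa`.

## Known limitations

* βNTI on small phylogenies (≲200 tips) saturates; strongly negative
  values require sparse communities relative to the tree (see above).
* RC_bray's null is sensitive to the metacommunity definition; per-season
  versus pooled runs answer different questions and both are supported.
* Undefined βNTI pairs (degenerate nulls) are common when samples share
  all abundant taxa; fractions are reported over defined pairs only, with
  the undefined count alongside.
* The exact Spearman p-distribution is used only for ≤ 9 tie-free samples;
  with ties the t approximation is kept (exact-with-ties would require
  per-pair enumeration).
* PCNM axes are returned unselected; studies that forward-select axes by
  constrained ordination will retain fewer.
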