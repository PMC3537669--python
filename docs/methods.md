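# Methods

## Study design the package implements

The pipeline analyses a haploid biallelic cross: two parents, a panel of
genotyped segregants (alleles 0 = parent A, 1 = parent B; no
heterozygotes), an expression matrix over the same strains with parental
replicate measurements, a typed interactome over the expressed genes, and
optionally a compound-response screen (growth yields per compound ×
condition). All positions are 1-based inclusive base pairs.

## Heritability filter

H² = (σ²_seg − σ²_parents)/σ²_seg with σ²_parents the df-weighted pooled
within-parent replicate variance (the standard meaning of "pooled
variance"). σ²_seg = 0 yields an undefined record that is flagged, not an
exception, and excluded from the FDR family with p = 1. Significance:
segregant and parental values are pooled, reassigned at random to null
groups of the original sizes, and H² recomputed; p is the fraction of null
statistics ≥ the observed one (weak inequality). BH is applied across
traits by the caller/pipeline.

## Linkage testing

The pooled-variance (equal-variance) two-sample Student t is used
throughout, signed as mean(allele 1) − mean(allele 0); Welch's variant was
deliberately not made the default because group sizes in a cross are
near-balanced and the equal-variance form matches the analysis design. A
monomorphic marker raises; zero pooled variance with distinct means returns
±1e6 with a warning (a finite stand-in for an infinite statistic, large
enough to exceed any null yet safe in downstream arithmetic).

Permutation significance: per trait, `n_perm` (default 1,000) permutations
of the strain labels; the null |t| values are pooled across all markers of
the trait (genome-wide permutation tradition; per-pair pooling available
via `null_pooling="pair"`). p = #(null |t*| ≥ |t|)/pool size — the plain
frequency, so p = 0 can occur. The conservative (c+1)/(B+1) variant is
available (`conservative_p=True`) but is off by default, matching a design
that accepts p = 0.

A consequence worth knowing: under a global null the plain-frequency
convention produces p = 0 for some trait with probability ≈ T/(B+1) over T
traits, so BH on these p-values is slightly anti-conservative at small B.
At the design's B = 1,000 the effect is ~2% of replicates and the realized
false-discovery proportion stays within 1.5× nominal (verified in the
acceptance suite at B = 1,000 with freely recombining markers, where
true/false pairs are unambiguous). If you must run with B ≪ 1,000, switch
the conservative variant on.

Marker preprocessing: maximal runs of adjacent markers with identical
genotype vectors (NaN-aware equality) collapse to the run's first marker;
the merge map inverts the operation. Non-adjacent duplicates are never
merged. cis/trans: a hit is cis iff the marker sits on the trait gene's
chromosome within 10 kb (≤, strict boundary: 10,001 bp is trans) of the
gene's span; unplaced genes are "unknown".

Missing expression is imputed before mapping by k = 15 nearest rows
(nan-Euclidean distances over co-observed columns, mean of the neighbours'
values), via scikit-learn's KNNImputer.

## ASCP and ASDP

ASCP is purely combinatorial: one record per (marker, edge) where the
marker is a significant eQTL of both endpoints. Undirected edge keys are
canonicalized lexicographically so (a,b) and (b,a) are one interaction.

ASDP: Dys = |r⁰ − r¹|, the absolute change in the Pearson correlation of
the endpoints' expression between allele groups. Groups smaller than 3
strains, or with zero variance in either gene, are skipped with a logged
reason (Pearson r is degenerate below that). The permutation null
reassigns strains at random to two groups of the original sizes;
p = #(Dys* > Dys)/n_perm with *strict* inequality — note the contrast with
the weak inequality in linkage mapping; each follows its own stated
formula. BH is applied across all tested pairs and records with
q < fdr_level are kept.

Candidate universe: by default, (marker, edge) pairs where the marker is a
significant eQTL of at least one endpoint; a full marker × edge scan is
available (`candidate_mode="all"`) but quadratic. The CPN and DPN are the
unions of ASCP and ASDP edges; summary statistics (size,
largest-component fraction, degree sequence) are reported alongside.

## LD blocks and sub-networks

Blocks are called with a contiguous-r² rule suited to haploid biallelic
panels: walking along a chromosome, the next marker joins the current
block iff its minimum pairwise r² with every marker already in the block
is ≥ 0.8 (default). Blocks partition the marker list. An external
marker→block table can override the built-in rule, so block assignments
from any dedicated haplotype-block caller can be supplied.

A block's sub-network is the induced subgraph of the integrated network on
the endpoint genes of its perturbed edges (interpreting "the minimal
component containing all the genes" as the induced subgraph, not a Steiner
tree — connector genes beyond perturbed-edge endpoints are not added; this
reading guarantees every perturbed edge is present by construction).
Blocks perturbing fewer than `min_edges` (default 3) distinct edges are
dropped. The block × interaction association matrix is binary and
order-independent.

## Topology statistics and nulls

* Characteristic path length: mean shortest-path distance over unordered
  gene pairs of the set, measured in the **full** network's undirected
  simple view — not inside the induced subgraph — because sub-network gene
  sets are scattered in the interactome and their dispersion is the
  quantity of interest. Disconnected pairs are excluded and their fraction
  reported; an all-disconnected set is an error.
* Density: 2E/(N(N−1)) on the undirected simple view (parallel typed edges
  counted once).
* In-degree ratio: within-edges / boundary-edges; zero boundary edges is
  reported as a flagged infinity.

Null model: Maslov–Sneppen degree-preserving randomization, run per
interaction type (undirected double edge swaps; directed-edge swaps for
PDI/KPI preserving in- and out-degrees), rejecting swaps that create
self-loops or duplicates, until each edge is rewired `swaps_per_edge`
times on average (networkx's swap routines). Types with < 2 edges are left
unchanged with a warning. Z = (obs − null mean)/null sd; empirical
p = #(null ≥ obs)/n_random for density and in-degree ratio, ≤ for path
length (expected shorter). A same-size gene-resampling null
(`null="gene_resample"`) is also exposed; the edge-swap null is the
default.

CSR(i, j) = |Gᵢ ∩ Gⱼ|/|Gᵢ ∪ Gⱼ| over two blocks' sub-network gene sets;
the same-vs-different-chromosome contrast uses the two-sided Wilcoxon
rank-sum test (scipy's mannwhitneyu; the log transform applied for
presentation does not change a rank-based p).

## Compound response

Every compound × condition is an independent trait mapped with the same
permutation machinery; hits must pass the permutation FDR **and**
|t| > 3.28 strictly (a value exactly at the threshold is excluded).
Markers are unioned per compound. Bridging to network perturbations is at
LD-block resolution — an SMP QTL recruits all perturbed interactions of
eQTLs in its block — with exact-marker bridging available
(`bridging="marker"`). Every edge in a compound sub-network carries its
perturbing records, so provenance is machine-checkable.

## Enrichment

p = P(X > x) = 1 − F(x; m, n, k): the hypergeometric upper tail with the
observed count itself *excluded*. This strict convention is deliberate —
it makes x = m (all known targets captured) give p = 0 exactly — and the
conventional P(X ≥ x) is available via `inclusive=True`. Background
defaults to all interactome genes. BH q-values are computed across the
sets tested together as one family.

Candidate drug targets: genes outside every known target set that touch ≥
`min_links` (default 3) distinct known targets through perturbed edges in
compound sub-networks, reported with a per-compound link breakdown.

## Synthetic data

The generator emulates the panel structure the analysis was designed for;
defaults are 112 strains, 2,956 markers on 16 chromosomes at 4 kb spacing,
adjacent-marker recombination probability 0.02, a 6,064-gene interactome
with layer sizes {PPI 25,301; PDI 12,681; KPI 28,785; EEI 3,486}, noise SD
1, effect size 2 (in noise-SD units), 4 parental replicates per parent
(replicate count is configurable; only the heritability stage consumes
them), and a planted-ASDP correlation gap of 0.9.

* Genotypes: per strain and chromosome a two-state Markov chain (fair-coin
  start, switch probability = recomb_prob), which yields LD decaying with
  distance. recomb_prob = 0 gives uniform chromosomes; 0.5 gives free
  recombination.
* Expression: additive planted allele effects plus Gaussian noise.
  Planted ASDP pairs receive a shared latent factor in each allele group
  with loading √|r| (sign-split across the two genes for negative r), so
  within-group correlations hit the prescribed (r⁰, r¹) in expectation —
  an analytically controllable Dys. Planted ASDP markers are also made
  weak eQTLs of one endpoint so the default candidate universe reaches
  them.
* Interactome: degree-biased attachment with +1 smoothing, shared degree
  budget across layers (hubs are hubs in every type), rejection of
  self-loops and within-type duplicates; heavy-tailed by construction.
* Genes are placed at marker positions round-robin so cis relationships
  (≤ 10 kb) are constructible.
* Compound traits: one planted QTL marker per compound shifting every
  condition by 1.5 noise-SD by default; known-target gene sets are biased
  (~70%) into the network neighbourhood of the genes the compound's QTL
  perturbs.

What the generator does **not** emulate: realistic recombination maps and
hot/cold spots, epistasis, correlated measurement error across arrays,
batch effects, expression-level heteroscedasticity, and missing-genotype
structure. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to every
artefact of real expression data.

## Problem sizes in the test and acceptance suites

The unit and acceptance suites run scaled instances chosen as the smallest
panels at which each property is statistically identifiable: 112 strains
wherever a calibration or power claim is made (the design's panel size),
20–200 markers, 20–300 genes, B = 200–1,000 permutations, 200 random
networks for the planted-module topology check, and a 2,000-gene /
6,000-edge instance for the randomization mixing check. The end-to-end
pipeline check uses 50 strains, 200 markers, 300 genes and completes in
well under five minutes on one CPU.

## Known limitations

* The plain-frequency permutation p-value is anti-conservative at p = 0
  for small permutation counts (see Linkage testing); use the conservative
  variant if B must be small.
* The contiguous-r² block rule is a deliberate simplification; supply an
  external assignment for confidence-interval-based blocks.
* ASDP measures correlation change, not causal direction; no attempt is
  made to orient eQTL → edge effects.
* The full marker × edge ASDP scan is quadratic and should be reserved for
  small instances.
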