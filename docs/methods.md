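# Methods

This note documents the models the package implements, the defaults and why
they are set where they are, what the synthetic-data generators do and do
not emulate, and the numerical choices that matter for reproducing results.

## Mixed model and variance components

The trait model is

    y = μ + X_B b + X_R r + X_W w + X_M m + Z_g g + Z_gw gw + ε

with blocks, replicates, water levels (seasons) and measurement months as
fixed factors, genotype effects g ~ N(0, σg² I), genotype-by-water effects
gw ~ N(0, σgw² I) and residual ε ~ N(0, σε² I). Fixed factors with a single
level are dropped with a warning; a rank-deficient fixed design raises an
error naming the aliased columns.

REML estimation runs on Henderson's mixed-model equations. The first three
iterations are EM updates (monotone in the restricted likelihood, safe when
a component sits near zero); afterwards average-information (AI) Newton
steps are proposed and accepted only when they do not decrease the
likelihood, falling back to EM otherwise. The restricted log-likelihood is
evaluated through MME identities (determinant and quadratic-form
decompositions), which a unit test verifies against a direct dense
V = ZDZ' + σε²I computation to ~1e-13. Convergence is declared when
successive log-likelihoods differ by < 1e-8, capped at 500 iterations;
non-convergence is returned flagged. Variances are floored at
1e-10 × var(y). BLUPs of g and gw are read off the converged equations; an
independent cross-check fits the same model with statsmodels MixedLM and
agrees to ~1% on components and ~5e-3 on BLUPs.

Random effects are tested by a likelihood-ratio test whose null is the
50:50 mixture of χ²₀ and χ²₁ (one variance on the boundary). At a statistic
of exactly zero the p-value is 1 (the upper tail at 0 has full mass); it
approaches 0.5 as the statistic approaches zero from above.

Broad-sense heritability on a genotype-mean basis is
H² = σg² / (σg² + σgw²/s + σε²/a) with s environments and a blocks.

## Genotype QC and LD

Filtering keeps markers with missing rate ≤ 0.20 (strictly-more-than-20%
removed) and MAF ≥ 0.05 computed on non-missing calls; because per-marker
MAF does not depend on other markers, the two-stage and joint filters
coincide. kNN imputation (k = 5) ranks donors by Euclidean distance over
markers observed in both samples, scaled by the shared-marker count, with
ties broken by sample order; imputed dosages are rounded into {0, 1, 2}.

Population structure uses PCA on column-centred dosages and the VanRaden
genomic relationship matrix K = ZZ'/(2Σp(1−p)). LD is the squared Pearson
correlation of dosage columns (composite LD — appropriate for unphased
genotypes); monomorphic markers yield NaN, never 0. The decay curve
r² = a + b·e^(−c·d) is fitted by nonlinear least squares from a small grid
of starts (a ∈ {0, min r²}, c log-spaced in 1e-6…1e-2), keeping the lowest
SSE.

## Association scan

The scan follows the fixed/random alternation of the FarmCPU family:

- **Fixed-effect step.** Every marker is tested by OLS of the BLUP
  phenotype on [intercept, PCs, current pseudo-QTNs, marker], using the
  Frisch–Waugh residualisation so the whole genome is one vectorised pass;
  the t-test has n − p − 1 degrees of freedom. Markers collinear with the
  covariate block (including duplicates of a pseudo-QTN) report p = 1.
- **Random-effect step.** Candidate markers below a Bonferroni-type gate
  (0.01/m) are binned along the genome; the best marker per bin is kept,
  and the combination of bin size {5e5, 5e6, 5e7} bp and pseudo-QTN count
  {5, 10, 15} is chosen by the REML likelihood of a one-component mixed
  model on the pseudo-QTN kinship (eigendecomposition + 1-D bounded
  optimisation of the variance ratio). Kinship enters only here, as in the
  published method; nearly collinear pseudo-QTNs (|r| > 0.99) drop the
  later entrant.
- Iteration stops when the pseudo-QTN set repeats (max 10 rounds).
  Pseudo-QTNs receive their p-values from their covariate t-tests in the
  final joint model, so a selected causal marker is not blanked by its own
  presence in the covariate set.

The significance threshold permutes the BLUP vector 30 times (covariates
fixed), records the genome-wide minimum p of a single fixed-effect scan per
permutation, and takes the type-7 (linearly interpolated) 5% quantile of
the minima. With 30 permutations the quantile rule is visible: minima of
0.01·i give a threshold of 0.0245, not an order statistic exactly.

Per-SNP statistics are Va = 2p(1−p)α² and PVE = Va / var(BLUP phenotype),
rounded only in reports. LD expansion collects every marker (genome-wide)
with r² ≥ 0.7 to at least one hit; the hits themselves are excluded from
the snpsLD list but all qualifying pairs are kept as weighted edges of the
LD network.

## Marker annotation

"Upstream/downstream" is meant in genome-coordinate, strand-agnostic terms:
a marker inside a transcript is assigned to it at distance 0; otherwise the
nearest transcript ending before and the nearest starting after the marker
are reported with their bp gaps (ties broken toward the smaller start
coordinate). Because a mean assignment distance can be computed with or
without contained markers, both statistics are available. QTL-interval
overlap uses closed 1-based intervals.

## Coexpression network

Counts are converted to CPM; genes are kept when their mean CPM ≥ 10 (an
"any sample ≥ 10" rule is available by flag); retained values are
log2(CPM + 1) and quantile-normalised (each column's values replaced, in
rank order, by the across-sample mean of sorted values — an idempotent
transform).

The network is unsigned: a_ij = |cor|^β with zero diagonal. The scale-free
fit statistic bins connectivities into **log-spaced** bins before the
log10 p(k) vs log10 k regression and reports the R² signed negative when
the slope is positive. Log-spaced bins are a deliberate departure from
equal-width binning: on null data at high powers the connectivity
distribution collapses into a few occupied equal-width bins and scores as
spuriously scale-free, whereas log bins keep null fits low while still
certifying genuine power-law connectivity. The chosen β is the smallest
reaching fit ≥ 0.85, falling back (with a warning) to the argmax. Mean
connectivity is reported per β. A useful consequence probed by the tests:
data with only a handful of equal-sized modules is *not* scale-free and
correctly takes the fallback path.

TOM is the standard unsigned topological overlap
TOM_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with ℓ = A², unit
diagonal; a triple-loop oracle pins it to < 1e-10 on fixtures.

Modules come from UPGMA on 1 − TOM with an adaptive branch cut, the
package's simplified variable-height rule: a branch qualifies when it has
≥ 30 leaves and its gap to the parent merge exceeds both 3× the median of
its internal merge-height steps and 2× its final internal step (a loose
union of tight branches has a large final step and cannot swallow its
children). Nested qualifying branches are resolved greedily by descending
gap; the root never qualifies; remaining genes are unassigned. On white
noise this yields no modules; on planted blocks it recovers the partition
exactly in the test fixtures.

Modules containing a GWAS-assigned gene are selected; the seeded subnetwork
joins their genes with the snpsLD-assigned genes, connecting pairs with
|Pearson r| ≥ 0.5 (signed r as edge weight; pairwise-complete observations,
never with ≤ 2 shared samples). Hub scores are the Kleinberg hub vector —
the principal eigenvector of AᵀA of the |r|-weighted adjacency — normalised
to max 1; for a symmetric adjacency hub and authority coincide, computed by
symmetric eigendecomposition and cross-checked against power iteration to
1e-8.

## Enzyme network

EC numbers are harvested from the annotation (partial ECs with a trailing
`-` kept but flagged; malformed strings rejected with a warning). Every
pathway containing a query EC is retrieved and **all** its member enzymes
become nodes, so the network is much larger than the query set, including
disconnected members. Directed edges run product → substrate within a
pathway; the currency-compound exclusion list is fixed at ATP, ADP, NAD+,
NADH, NADP+, NADPH, H2O, H+, CO2, Pi, PPi, CoA, O2 (without it nearly every
enzyme pair connects). Reversible reactions (when the database marks them)
double edges; the default is irreversible.

Topology: degrees on the directed graph; betweenness (normalised by
(n−1)(n−2)/2), stress (exact integer shortest-path counts via per-source
BFS σ-counts), eccentricity and per-node mean shortest path within each
connected component; neighbourhood connectivity as the mean in+out degree
of a node's neighbours; the diameter is the largest component's maximum
eccentricity. Distances are unweighted hops; infinite distances never enter
means. Because the mean-neighbour count can be read off the undirected
simple graph (2E/N) or the directed multigraph, both conventions are
reported. Hubs are Tukey outliers: total degree > Q3 + 1.5·IQR.

Communities approximate pan-resolution persistence (the core idea of
HiDeF): Louvain modularity partitions at 20 log-spaced resolutions in
[0.1, 10], communities chained across consecutive resolutions by Jaccard
≥ 0.75, and reported when they persist ≥ 2 consecutive resolutions with
≥ 4 members. Per-community betweenness/stress/eccentricity are computed on
the community-contracted graph. Full containment-graph reconstruction is
out of scope.

## Synthetic data

All generators are pure functions of their integer seed.

- **Genotypes.** Each LD block copies a latent haplotype and flips each
  marker's allele independently with probability f; under symmetric
  flipping the marker–latent correlation is 1 − 2f at allele frequency 0.5,
  so f is solved from the block's target pairwise r² as
  f = (1 − r²^{1/4})/2. Blocks marked TE-dense use the target scaled by
  0.25 (the qualitative observation is only that TE-rich regions show lower
  LD). Two haplotypes per sample are summed into dosages; missingness is
  injected uniformly (default 5%). Away from allele frequency 0.5 the
  realised r² sits slightly below target — a documented approximation.
- **Phenotypes.** Exactly the mixed model above, with deterministic centred
  fixed-effect values per level and defaults at the study-scale variance
  components (4.56, 0.0001, 26.69 cm²; 437 genotypes × 8 records in the
  recovery tests). Planted QTL effects α enter the genotype effect's mean,
  so the stated σg² is the *residual* polygenic variance and each QTL adds
  2p(1−p)α² on top.
- **Expression.** One latent factor per module; module k's factor is the
  standardised dosage of planted QTL k when the expression samples come
  from the genotyped panel, tying modules to QTL genotypes. Gene profiles
  are √c·factor + √(1−c)·noise, pushed through a negative binomial
  (dispersion 0.1, log-normal per-gene baselines and library factors), so
  observed log-CPM correlations sit slightly below the nominal c. CPM is
  compositional: if planted modules form most of the library, their factor
  swings move the library size and induce strong negative between-module
  correlations that no unsigned network can separate — recovery fixtures
  therefore surround modules with background genes, as in a real
  transcriptome where any module is a small fraction of the library.
- **Pathways.** A KEGG-like flat table; with probability
  `shared_compound_rate` a reaction consumes an earlier product (chaining
  the enzyme graph), and currency cofactors are appended to a configurable
  fraction of reactions to exercise the exclusion list.

What passing recovery tests show: the pipeline detects additive planted
signal under Gaussian noise, block-structured LD and factor-structured
expression at the stated sizes. What they do not show: robustness to
non-Gaussian traits, related-sample confounding beyond the simulated
structure, isoform-level expression complexity, or real KEGG topology.

## Problem sizes and numerics

The test suite runs REML recovery at 437 genotypes × 8 records
(20 replicates), GWAS power and error control at n = 300, m = 2,000
(20 power seeds, 50 null datasets with 30 permutations each), module
recovery on 150 module + 300 background genes (10 seeds), and exact-oracle
sweeps over all connected graphs on ≤ 5 nodes plus twenty 12-node random
graphs — sizes chosen so the planted effects are comfortably identifiable
while the whole suite stays fast. Power simulations plant the QTL inside
r² = 0.8 LD blocks, emulating the high genome-wide LD this kind of clonal
tree population shows; in much looser blocks the scan still finds the
signal region, but the block neighbour taking the minimum p can fall below
the r² ≥ 0.7 credit line of the detection definition.

Known limitations: the FarmCPU simplification fixes its bin/count grids
rather than adapting them; the variable-height tree cut is a documented
stand-in, so absolute module counts on real data will differ from the
reference heuristic; the enzyme network derives edges only from within-
pathway compound sharing; and printed heritability values are not
reproducible from printed variance components without knowing the (s, a)
the original analysis used, so H² is exposed as a formula, not a target.
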