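# Methods

This note documents the statistical conventions, the synthetic-data model,
and the design decisions behind nitronet. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Diversity indices

Per sample, with proportions pᵢ = xᵢ/Σx over observed OTUs:

- **Shannon** H = −Σ pᵢ ln pᵢ (nats).
- **Gini–Simpson** 1 − Σ pᵢ². This is the "simpson" most amplicon
  pipelines report; dialects differ (some report Σ pᵢ² or its inverse),
  so the choice is stated prominently here.
- **Pielou** J = H / ln S with S the observed richness; undefined (NaN,
  flagged) when S < 2.
- **Chao1** S + F₁²/(2F₂) with F₁/F₂ the singleton/doubleton counts, or
  the bias-corrected S + F₁(F₁−1)/2 when F₂ = 0. Computed on raw integer
  counts; no rarefaction is performed anywhere in the package (a
  deliberate simplification — Chao1 in particular is depth-sensitive, so
  cross-study comparisons should rarefy externally if needed).

## Dissimilarity, ordination, permutation tests

**Bray–Curtis** on relative abundances is the default community
dissimilarity (Jaccard on presence/absence by flag). **PCoA**
eigendecomposes the Gower-centred matrix −½JD²J; negative eigenvalues are
retained in the eigenvalue list but contribute no coordinates, and no
Lingoes/Cailliez correction is applied by default. Proportion explained
is taken over positive eigenvalues.

**PERMANOVA** uses the distance-based sums of squares
SS_T = (1/N)Σ_{i<j} d²ᵢⱼ and SS_W = Σ_g (1/n_g)Σ_{i<j∈g} d²ᵢⱼ, with
pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)) and R² = SS_A/SS_T. Sampled
permutation p-values always use the add-one rule
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm); an exact mode enumerates all
relabelings for small n (then p is the plain fraction including the
identity). Note that for tiny balanced designs the attainable p floor is
set by the number of label permutations that reproduce the same
partition (e.g. ~0.1 for 3 vs 3), not by 1/(1+n_perm).

**Dispersion homogeneity** embeds samples by PCoA keeping the
negative-eigenvalue axes separately; the squared distance to the group
centroid is the positive-axis part minus the negative-axis part, floored
at zero before the square root. The one-way F statistic on these
distances is tested by permuting group labels over the fixed distances
(centroids are not recomputed per permutation — a simpler null than
vegan's `permutest`, documented here as this package's convention).

**SIMPER** decomposes each between-group pair's Bray–Curtis dissimilarity
into per-taxon terms |x_{ik} − x_{jk}|/Σ_m(x_{im} + x_{jm}) on relative
abundances, which sum exactly to the pair's dissimilarity; averaging over
all between-group pairs and normalising gives percent contributions.
Because relative abundances are compositional, a change confined to one
taxon's counts necessarily induces compensating contributions from the
others; a single taxon can therefore never carry 100% of the
dissimilarity except in degenerate cases.

**Group tests** are Kruskal–Wallis (tie-corrected; H defined as 0 with
p = 1 when all values are identical) plus pairwise two-sided Wilcoxon
rank-sum tests — exact when both groups have n ≤ 8 and no ties, otherwise
the tie- and continuity-corrected normal approximation — with BH
correction applied across taxa within each test family.

## Taxon–environment association

Preference profiles correlate each taxon's relative abundance (phylum
level by default, OTU level by flag) with each soil property by Spearman
rank correlation (t-approximation p-values). BH correction pools all
(taxon, property) pairs into one decision family, matching the single
"ecological preference" question being asked; sign labels
(positive/negative) are assigned only at q ≤ threshold. Constant
properties are excluded with a warning.

Mantel tests correlate the strictly-upper-triangle vectors of two
distance matrices (Spearman by default) and permute the rows and columns
of the second matrix *jointly* — never triangle entries independently,
which would destroy the within-matrix dependence structure and produce a
much narrower null. For per-phylum tests the community matrix is
Bray–Curtis over the phylum's OTUs and the environment matrix is
Euclidean distance on z-standardized properties; both metrics are
package conventions (field-standard, but not uniquely determined by the
workflow this package reimplements). Phyla with fewer than two OTUs have
a degenerate (constant) composition and are skipped; a degenerate
distance matrix yields a flagged NaN result rather than a number.

## Co-occurrence networks

Built per pooled treatment pair (e.g. N800+N600, N600+N400, N400+N0).
Steps and conventions:

1. **Prevalence filter** (default: present in ≥ 50% of the pooled
   samples). All-pairs Spearman on sparse OTUs produces tie-driven
   spurious edges; the filter is overridable to 0 to mimic an unfiltered
   analysis.
2. **Correlation screen**: all-pairs Spearman on relative abundances
   (raw-count mode by flag), two-sided t-approximation p-values, no
   multiple-testing correction on edge p-values (a BH flag exists but
   defaults off). Constant OTUs are flagged and excluded.
3. **Edges** where p < 0.01 and |ρ| > 0.6, both strict; the signed ρ is
   the edge weight. Isolated nodes are dropped.
4. **Topology**: average degree 2E/N; average weighted degree
   mean_i Σ_j |w_ij|; mean unweighted local clustering (0 for degree < 2);
   modules by greedy agglomerative modularity maximization on the
   canonicalised (sorted) unweighted graph, which makes the partition
   deterministic — chosen over Louvain precisely because Louvain's output
   varies across runs; Q reported for that partition; edge-sign fractions
   over all edges.
5. **Natural connectivity** λ̄ = ln((1/N)Σ exp(λᵢ)) from the unweighted
   adjacency spectrum, computed by symmetric dense eigendecomposition
   with log-sum-exp (overflow-safe for λ₁ in the hundreds). Dense
   eigensolves are comfortable at the 10²–10³-node scale these networks
   reach.
6. **Robustness**: for each removal fraction f, ⌊fN⌋ nodes are removed
   uniformly at random; natural connectivity and average degree of the
   induced remainder are averaged over replicates (default grid
   0.05–0.50 step 0.05, 100 replicates, seeded). A fraction removing zero
   nodes returns the intact values with sd 0.
7. **Zi–Pi**: Zᵢ standardises within-module degree with the *population*
   standard deviation (the convention of the original role-taxonomy
   literature), with Zᵢ = 0 for modules with sd 0 or fewer than two
   members; Pᵢ = 1 − Σ_t (k_{it}/k_i)², 0 for isolated nodes. Roles:
   network hub (Z > 2.5, P > 0.62), module hub (Z > 2.5, P ≤ 0.62),
   connector (Z ≤ 2.5, P > 0.62), else peripheral.
8. **Network comparison**: Jaccard dissimilarity 1 − |∩|/|∪| on node sets
   and on unordered unweighted edge sets — a labeled assumption, since
   "network dissimilarity" has no single standard definition.

## The synthetic community model

`generate_community` draws, per sample in treatment level g (level 0 =
highest fertilization):

1. Dominant-taxon expected fraction λ_g = `dominance_base` +
   g·`dominance_slope` (defaults 0.6 and −0.08, giving 0.60 → 0.36 across
   four levels — the magnitude of dominant-phylum decline reported in
   fertilization-gradient studies of this design).
2. A non-dominant mean composition: planted block members share a common
   baseline weight, background OTUs get a lognormal(0, 1) abundance
   spectrum. Each block's members are multiplied by
   exp(`block_loading`·f) with f ~ N(0,1) drawn per sample per block,
   then renormalized — inducing positive within-block rank correlations
   that survive compositional closure.
3. A Dirichlet draw with concentration `overdispersion` (default 2000)
   around that mean, then multinomial counts at Poisson(`depth`) total
   (default 20,000 reads).
4. Soil properties: intercept + slope·g + N(0, `noise_sd`·|slope|), with
   pH and SOM rising and TN/AP/AK/AN/NH₄/NO₃ falling along the gradient.
   The per-property noise scales with the slope so signal-to-noise is
   uniform across properties whose units differ by orders of magnitude —
   a deliberate reading of "one noise knob" that keeps a single
   dimensionless parameter meaningful for pH (≈6) and AK (≈150 mg/kg)
   alike.

Default `overdispersion` is high (concentration 2000, i.e. mild
compositional noise) because in this model the *latent factor loading* is
the intended knob for co-occurrence signal strength; pushing residual
Dirichlet noise up instead would conflate the two. Marginally realistic
amplicon overdispersion (concentration in the tens) is reachable by
lowering the knob.

**What the generator does and does not emulate.** It reproduces the
statistical signatures the analysis stages consume: a dominance gradient
(hence rising evenness), planted correlation blocks (hence recoverable
network modules), treatment-coupled environmental covariates, and
Dirichlet-multinomial count noise. It does not simulate reads, chimeras,
OTU-calling artifacts, phylogenetic structure, temporal dynamics, or
realistic taxon abundance distributions beyond a lognormal background —
so passing recovery tests demonstrates correctness of the inference
machinery under the stated model, not performance on real soil data.

**Validation design.** Planted-structure recovery (edge precision/recall
and module ARI against the generator truth) is evaluated on communities
with `dominance_slope = 0`. With a sloped gradient, the shared (1 − λ_g)
scaling of the whole non-dominant pool induces genuine co-abundance
among background OTUs — real correlation, but not planted-block
correlation — which makes "precision against planted pairs" the wrong
score for the inference machinery. The flat-gradient design isolates the
planted structure; the gradient's own effects are validated separately by
the direction test (Shannon/Pielou strictly increasing, PERMANOVA
detecting the treatment) and the null calibration (PERMANOVA type-I error
at nominal 0.05 over 300 structure-free simulations of 12 samples × 50
OTUs). ARI is computed over planted-block nodes only, because background
OTUs carry no planted module label. Measured over 20 generator seeds
during development, these conditions give within-block edge precision
≥ 0.94 and recall ≥ 0.92, with block-restricted ARI 1.0.

Problem sizes used by the default test suite and acceptance script —
4 treatments × 10 replicates, 150 OTUs, depth 20,000 for gradient runs;
12 × 50 for null calibration — keep every check fast while leaving all
statistical conclusions comfortably away from their thresholds.

## Numerical and degenerate-input conventions

- Distance matrices are validated symmetric to 1e-12 and re-symmetrized
  exactly; diagonals must be exactly zero.
- Permutation tests compare with a 1e-12 tolerance on the "≥ observed"
  side so bit-level noise in permuted statistics cannot flip a count.
- Edge thresholds are strict inequalities; ρ = 0.6 exactly forms no edge.
- Samples with zero total counts are rejected at read time (override
  flag available) because every downstream index divides by row totals.
- Greedy-modularity input graphs are canonicalised (sorted nodes/edges)
  before community detection; module ids are assigned by decreasing
  module size with lexicographic tie-breaks, so partitions, Q, and module
  counts are reproducible run to run.
- Per-stage seeds in the pipeline are spawned from the master seed via
  `numpy.random.SeedSequence`; no stage touches global RNG state.

## Known limitations

- Spearman + threshold networks ignore compositionality;
  SparCC/SPIEC-EASI-style compositional inference is out of scope.
- The dispersion test's label-permutation null is simpler than vegan's
  centroid-recomputing permutation; p-values can differ slightly for
  small unbalanced designs.
- Edge p-values are raw by design (mirroring the p < 0.01 convention);
  with thousands of OTU pairs this admits a known false-edge rate.
- UniFrac and other phylogeny-aware distances, rarefaction curves, and
  structural equation modeling are intentionally not provided.
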