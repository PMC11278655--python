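# nitronet

Desk-side statistical analysis of soil bacterial communities along
nitrogen-fertilization gradients: alpha/beta diversity with permutation
statistics, taxon–environment association, and thresholded Spearman
co-occurrence networks with robustness and keystone (Zi–Pi) analysis —
plus a synthetic-data generator that emulates the *competitive release*
structure such studies report, so every stage of the pipeline can be
validated without sequencing data.

## Who this is for

Microbial ecologists who have an OTU count table (samples × OTUs), a
taxonomy map, and per-sample metadata (treatment label such as
N800/N600/N400/N0 plus soil properties pH, SOM, TN, AP, AK, AN,
NH₄⁺-N, NO₃⁻-N) and want a reproducible, scriptable version of the usual
vegan/psych/Gephi workflow with explicit seeds and a provenance manifest.

## What it computes

**Diversity.** Shannon *H* = −Σ pᵢ ln pᵢ, Chao1 = S + F₁²/(2F₂),
Gini–Simpson 1 − Σ pᵢ², Pielou *J* = *H*/ln S; Bray–Curtis dissimilarity
d(u,v) = Σ|xᵤₖ − xᵥₖ| / Σ(xᵤₖ + xᵥₖ) on relative abundances; PCoA by
eigendecomposition of the Gower-centred matrix; one-way PERMANOVA
(pseudo-F, R²) with label-permutation p-values; betadisper-style
dispersion homogeneity; Kruskal–Wallis / pairwise Wilcoxon rank-sum with
Benjamini–Hochberg correction; SIMPER decomposition of between-group
dissimilarity into per-taxon contributions.

**Taxon–environment association.** Spearman preference profiles of each
taxon against each soil property with joint BH correction, and Mantel
tests (joint row/column permutation) between per-phylum Bray–Curtis
matrices and Euclidean distances on standardized properties.

**Co-occurrence networks.** For each pooled treatment pair: prevalence
filter → all-pairs Spearman screen → edges where *p* < 0.01 and
|ρ| > 0.6 (strict). Per network: average degree, average weighted degree
(mean Σ|w|), unweighted clustering coefficient, greedy-modularity modules
and Q, edge-sign fractions; stability as natural connectivity
λ̄ = ln((1/N) Σ exp(λᵢ)) under random node removal; keystone roles from
the within-module degree z-score Zᵢ and participation coefficient Pᵢ at
the 2.5 / 0.62 thresholds (peripheral, connector, module hub, network
hub); Jaccard node/edge dissimilarity between networks.

**Synthetic communities.** A Dirichlet-multinomial generator with a
dominant taxon whose expected fraction declines linearly along the
gradient (so evenness and Shannon rise as dominance falls), planted
latent-factor OTU blocks that become co-occurrence modules, and soil
properties coupled linearly to treatment (pH up, nitrogen pools down).
The generator returns its ground truth, which the test suite uses for
recovery checks.

## Worked example

```python
from nitronet import (SyntheticConfig, generate_community, alpha_diversity,
                      bray_curtis, permanova, paired_networks, topology)

cfg = SyntheticConfig(replicates_per_treatment=10, seed=42)
table, meta, tax, truth = generate_community(cfg)

alpha = alpha_diversity(table)
print(alpha.join(meta.treatment).groupby("treatment")[["shannon", "pielou"]]
      .mean().loc[["N800", "N600", "N400", "N0"]].round(3))

res = permanova(bray_curtis(table), meta.treatment, n_perm=999, seed=0)
print(f"PERMANOVA pseudo-F = {res.statistic_value:.2f}, "
      f"R2 = {res.effect_size:.3f}, p = {res.p_value:.3f}")

nets = paired_networks(table, meta,
                       [("N800", "N600"), ("N600", "N400"), ("N400", "N0")],
                       tax=tax)
for net in nets:
    topo, _ = topology(net)
    print(f"{net.label}: {topo.n_nodes} nodes, {topo.n_edges} edges, "
          f"Q = {topo.modularity:.3f}, +edges = {topo.positive_edge_fraction:.2f}")
```

Output:

```
           shannon  pielou
treatment
N800         2.537   0.507
N600         2.942   0.587
N400         3.315   0.662
N0           3.628   0.724
PERMANOVA pseudo-F = 16.68, R2 = 0.582, p = 0.001
Network 1: N800+N600: 115 nodes, 233 edges, Q = 0.811, +edges = 0.89
Network 2: N600+N400: 126 nodes, 255 edges, Q = 0.770, +edges = 0.85
Network 3: N400+N0: 122 nodes, 285 edges, Q = 0.723, +edges = 0.74
```

Mean Shannon and Pielou increase monotonically as the dominant taxon's
share falls from 0.60 (N800) to 0.36 (N0) — diversity and evenness rise
under reduced dominance. PERMANOVA confirms the treatment effect
(R² = 0.58 of the Bray–Curtis variation, p at the permutation floor), and
the pooled-pair networks gain edges toward the low-nitrogen end of the
gradient.

The same analyses are available from the shell via the `nitronet`
console script (subcommands: `simulate`, `alpha`, `beta`, `permanova`,
`betadisper`, `simper`, `preferences`, `mantel`, `network`, `robustness`,
`zipi`, `compare`, `run`); `nitronet run --config pipeline.yaml --outdir out/`
executes everything from one YAML config and writes a manifest with
per-stage seeds and SHA-256 checksums of every output.

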