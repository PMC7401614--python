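# aridinet

Analysis toolkit for soil/plant microbiome surveys along an **ordered
aridity gradient**: four bioclimatic zones (humid → semi-arid → upper-arid
→ lower-arid), each sampled at several sites in two root compartments
(rhizosphere soil and root endosphere), with per-site soil physicochemical
measurements.  It is written for microbial ecologists who want the full
chain — diversity summaries, ordination, gradient-trend screening of OTUs,
and an environment-aware co-occurrence network — as a reproducible,
scriptable pipeline rather than a collection of one-off notebook cells.

## What it computes

Given an OTU count table *X* (OTUs × samples), sample metadata
(compartment, zone, site) and a per-site soil table:

* **Alpha diversity** on counts rarefied to a common depth (default 1000
  reads): Shannon *H* = −Σᵢ pᵢ log₂ pᵢ (bits), Gini–Simpson 1 − Σᵢ pᵢ²,
  and observed-OTU richness; one-way ANOVA and Tukey HSD across groups.
* **Beta diversity**: Bray–Curtis dissimilarity
  BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on relative abundances, non-metric MDS
  (Kruskal stress-1, best of 20 random restarts), and PERMANOVA
  (Anderson's pseudo-F, permutation p with 5000 permutations by default,
  exhaustive enumeration available for small n).
* **Gradient-trend classification**: each sufficiently abundant OTU
  (pooled relative abundance > 0.1%) is labeled *increased* if the
  correlation r between its abundance and the zone rank (humid = 0 …
  lower-arid = 3) strictly exceeds +0.9, *decreased* if r < −0.9, else
  *neutral*.  Pearson or Spearman; per-sample or zone-mean profiles;
  humid-referenced ratio profiles are reported for inspection.
* **Co-occurrence network**: site-level abundances of the
  increased/decreased OTUs from both compartments plus the nine soil
  parameters (pH, humidity, TP, TOC, TN, Fe³⁺, Ca²⁺, K⁺, CEC) are
  correlated pairwise (Pearson and Spearman); p-values are
  Benjamini–Hochberg adjusted per method; an edge requires |r| ≥ 0.9 and
  q ≤ 0.05.  Positive edges are co-presence, negative are mutual
  exclusion.  The network splits into increased / decreased subnetworks,
  and nodes are ranked by degree to nominate hub (keystone) taxa.
* **Synthetic data**: a Dirichlet-multinomial generator with planted
  monotone OTUs, configurable effect sizes and gradient-correlated soil
  covariates, so every stage can be validated against known truth.  A
  19-site reference soil survey ships as a fixture.

## Worked example

```python
import aridinet as an

cfg = an.SyntheticConfig(seed=7)               # 300 OTUs, 4 zones x 3 sites x 3 samples x 2 compartments
counts, metadata, taxonomy, soil, truth = an.generate_dataset(cfg)
rel = an.relative_abundance(an.filter_organelle_otus(counts, taxonomy))

alpha = an.alpha_diversity(an.rarefy(counts, depth=1000, seed=7))
d = an.bray_curtis(rel)
res = an.permanova(d, metadata["compartment"], permutations=5000, seed=7)
emb = an.nmds(d, k=2, n_restarts=20, seed=7)

trends = {c: an.classify_trend(rel, metadata, c) for c in an.COMPARTMENTS}
features = an.build_feature_vectors(rel, metadata, trends, soil, taxonomy)
net = an.CooccurrenceNetwork(r_min=0.9, alpha=0.05, p_mode="bh").fit(features)
```

This prints / yields:

```
alpha (first 3 samples):
       shannon  simpson  observed_otus
H1_r1    6.165    0.976            161
H1_r2    6.143    0.975            164
H1_r3    5.885    0.969            149
PERMANOVA compartment: pseudo-F = 54.18, p = 0.0002
NMDS stress = 0.036
rhizosphere {'excluded_low_abundance': 165, 'neutral': 113, 'increased': 10, 'decreased': 10}
endosphere  {'excluded_low_abundance': 176, 'neutral': 102, 'increased': 10, 'decreased': 10}
network: 49 nodes, 1002 edges
```

Reading the numbers: the two compartments host clearly distinct
communities (large pseudo-F, p near the permutation floor of 1/5001); the
two-dimensional NMDS embedding is faithful (stress ≪ 0.1); the trend
screen recovers exactly the 10 + 10 planted monotone OTUs per compartment
with no false calls among the neutral majority; and the resulting network
links gradient responders to each other and to the soil gradient.

The same pipeline runs from the shell:

```bash
aridinet simulate --out-dir data --seed 7
aridinet run --otu data/otu_table.tsv --metadata data/metadata.tsv \
             --taxonomy data/taxonomy.tsv --soil data/soil.tsv \
             --out results/run --seed 7
```

writing `alpha.tsv`, `bray_curtis.tsv`, `nmds.tsv`, `permanova.tsv`,
`venn.tsv`, `trends.tsv`, `edges.tsv`, `network.graphml`, `network.sif`,
`hubs.tsv` and a `manifest.json` with a SHA-256 digest of every artifact.

## Layout

```
src/aridinet/
  io.py          readers/writers (TSV, BIOM 2.x), organelle filter,
                 relative abundance, taxonomy aggregation
  diversity.py   rarefaction, alpha diversity, ANOVA/Tukey, dominant OTUs,
                 zone-wise Venn partition
  ordination.py  Bray-Curtis, NonmetricMDS, PERMANOVA
  trend.py       GradientTrendClassifier and helpers
  network.py     CooccurrenceNetwork, BH-FDR, subnetworks, hubs, export
  simulate.py    synthetic generator + reference soil/zone fixtures
  pipeline.py    end-to-end orchestration with manifest
  cli.py         `aridinet` command-line entry points
```

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
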