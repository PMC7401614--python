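# Methods

## The analysis model

The package treats an aridity-gradient microbiome survey as four linked
questions:

1. *How diverse is each community?*  Alpha diversity is computed on counts
   rarefied (subsampled without replacement) to a fixed depth so that
   richness is not confounded with sequencing effort.  Shannon entropy is
   reported in bits (log base 2, the convention of common amplicon
   tooling; natural log is available), and Simpson as the Gini–Simpson
   index 1 − Σp² (the probability two random reads differ; the dominance
   form Σp² is available).  Group differences use classical one-way ANOVA
   and Tukey HSD (Tukey–Kramer under unequal group sizes).
2. *Do communities differ by compartment and zone?*  Bray–Curtis
   dissimilarities on relative abundances, visualized by non-metric MDS
   and tested by PERMANOVA.
3. *Which taxa track the gradient?*  A correlation-threshold screen
   (below), deliberately mirroring a descriptive field rule rather than a
   formal differential-abundance test.
4. *How do gradient responders co-occur with each other and with soil
   chemistry?*  An all-pairs correlation network with magnitude and FDR
   thresholds, split into increased/decreased subnetworks, with hub taxa
   ranked by degree.

## Gradient-trend classification

Zones are ranked 0–3 by increasing aridity (humid = 0, semi-arid = 1,
upper-arid = 2, lower-arid = 3, the order of decreasing annual
precipitation).  For each compartment, an OTU with pooled mean relative
abundance above 0.1% is labeled by the correlation r between its
abundance and zone rank: **increased** iff r > 0.9, **decreased** iff
r < −0.9 (both strict), otherwise **neutral**; constant profiles map to
r = 0.  OTUs at or below the abundance floor are tagged
`excluded_low_abundance` rather than silently dropped.

Two profile modes exist, and the choice matters:

* `samples` (default): r is computed across all samples of the
  compartment, each sample carrying its zone rank.  With n = 36 samples
  the null distribution of r is tight (sd ≈ 1/√33), so |r| > 0.9 is
  essentially unreachable by noise and the screen has a negligible
  false-positive rate.
* `zone_means`: r is computed on the four zone-mean abundances against
  (0, 1, 2, 3).  This matches zone-level summary plots, but with n = 4
  points the null density of Pearson r is ∝ (1−r²)^((n−4)/2) — exactly
  uniform on [−1, 1] — so |r| > 0.9 passes 10% of pure-noise profiles
  *regardless of noise level*.  The mode is provided for inspection and
  comparison, not for error-controlled screening, and this is why it is
  not the default.

Pearson is the default statistic; Spearman is available but note that on
4-point zone-mean profiles it is quantized (|ρ| = 1 for any strictly
monotone profile).  Ratio profiles against the humid zone mean are
emitted alongside r so a humid-referenced reading of "increased" is
auditable; when the humid mean is zero, a pseudo-abundance of half the
smallest non-zero proportion in the compartment is used for the ratio
only, never for classification.

## Co-occurrence network

Features are site-aligned vectors: for every increased/decreased OTU in
each compartment, the mean relative abundance across that site's samples
of the compartment; for each of the nine soil parameters, the site value.
All unordered pairs are correlated with Pearson *and* Spearman; p-values
come from the classical correlation nulls and are Benjamini–Hochberg
adjusted within each method's family of all tested pairs.  An edge exists
when at least one method reaches |r| ≥ 0.9 (inclusive) with adjusted
p ≤ 0.05; the qualifying method with the larger |r| annotates the edge,
and the edge sign is the sign of that r.  Design choices that were
genuinely open, and how they were resolved:

* **Either-method-qualifies (OR) rule** by default; an AND mode exists.
  The OR rule is the permissive reading of "Pearson/Spearman" screens
  common in co-occurrence studies.
* **BH-adjusted p by default** (`p_mode="bh"`); `raw` exists because some
  published networks threshold unadjusted p.
* **Site-level correlation** is the default because soil chemistry exists
  once per site; a pair needs ≥ 3 aligned sites, and zero-variance
  features are skipped with a log message.
* **Hub degree is counted on the full network**, not within a
  subnetwork, since hub tables typically mix increased and decreased
  taxa; `rank_hubs` keeps nodes with degree ≥ 56 and reports the top 22
  by default (ties broken by node id).
* **Subnetwork split**: the increased (decreased) subnetwork holds that
  class's OTU nodes plus soil parameters adjacent to them, with the edges
  touching the class and not the other one.  Increased–decreased edges
  and soil–soil edges are reported as separate lists, so the four blocks
  exactly partition the edge set (a three-way partition would miscount
  whenever two environmental parameters correlate with each other).

No compositionality correction (SparCC/SPIEC-EASI style) is applied: the
method is a plain correlation screen by design, and its compositional
caveats are inherited knowingly (see Limitations).

## PERMANOVA

Anderson's pseudo-F is computed directly from squared distances:
SS_total = Σ_{i<j} d²ᵢⱼ / n, SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ / n_g,
F = (SS_among/(k−1)) / (SS_within/(n−k)).  Monte-Carlo p-values use the
(b+1)/(B+1) estimator over B label permutations (default 5000, free
permutation, no strata — no blocking structure is modelled); for small n
an exhaustive mode enumerates every label ordering and returns the exact
proportion.  The implementation is cross-checked in the test suite
against scikit-bio's PERMANOVA (statistic equality) and against
brute-force enumeration (p equality), and its null p-distribution is
verified uniform by a KS test.

## Non-metric MDS

Kruskal stress-1 minimized by SMACOF with monotone regression
(scikit-learn backend), best configuration over 20 random restarts drawn
from a single seed sequence, so stress is non-increasing in the number of
restarts and runs are reproducible.  Distances that embed exactly in the
target dimension reach stress < 10⁻³.

## Synthetic data generator

The generator realizes the structure the analysis assumes — monotone zone
trends, replicate noise, compositionality — with known truth:

* **Design**: 4 zones × 3 sites × 3 samples per site per compartment
  (36 samples per compartment, 72 in total), depth 5000 reads.  The humid zone gets the same number of sites as the
  others so that group tests are well posed (real surveys often have a
  single humid site; the generator is configurable down to that).
* **Base composition**: lognormal(σ = 1.5) relative abundances over 300
  OTUs — a heavy-tailed community in which the top decile carries most
  of the mass, as in real 16S surveys.
* **Planted signal**: 10 increased + 10 decreased OTUs; increased OTUs
  are multiplied by fold^rank (fold = 2) before renormalization,
  decreased by fold^(3−rank).  Planted labels are drawn among OTUs whose
  per-compartment abundance lies in [0.4%, 2%]: responders must clear
  the 0.1% eligibility cutoff with margin in *both* compartments (the
  screen is per compartment), but must not collectively dominate the
  community — a large planted mass swings the renormalization
  denominator across zones and flattens every profile, which is both
  unrealistic and destructive to any gradient signal.  The planted count
  is deliberately small for the same reason: responders in gradient
  surveys are a minority of measurable OTUs.
* **Counts**: Dirichlet-multinomial with intraclass correlation
  θ = 2×10⁻⁴ (concentration p(1−θ)/θ), i.e. mild overdispersion beyond
  multinomial sampling.  The default configuration is calibrated so that
  the planted fold-2 signal is recoverable by the strict r > 0.9 rule —
  the package's own end-to-end recovery check — which bounds admissible
  replicate noise from above; heavier dispersion (θ ≳ 10⁻³, common in
  cross-subject human datasets) visibly attenuates per-sample
  correlations below the threshold at this effect size and depth.
* **Compartment structure**: each OTU carries a lognormal(σ = 0.75)
  compartment preference, so rhizosphere and endosphere communities are
  correlated but distinct and separate cleanly in ordination.
* **Soil covariates**: value = μ + σ·(s·ρ·z + √(1−ρ²)·ε) with z the
  standardized zone rank, ρ = 0.9 and signs s matching the directions
  reported for this gradient (humidity, TP, TOC, Fe, K, CEC decline; Ca
  rises; pH and TN flat); magnitudes echo the reference survey.  Note
  the reference table's raw K⁺ values actually *rise* toward the arid
  zones even though the accompanying text and network describe K⁺ as
  declining/anti-correlated with humidity; the fixture keeps the printed
  values and the generator follows the described direction — the
  discrepancy is surfaced here rather than silently "corrected".
* **Organelles**: two planted chloroplast-annotated OTUs exercise the
  organelle filter end to end.

What the generator does **not** emulate: phylogenetic correlation between
taxa, site-level random effects (samples are exchangeable within a zone
apart from the site grouping), spatial autocorrelation between sites,
zero-inflation beyond what Dirichlet-multinomial produces, and any
taxonomy–abundance association.  Passing recovery tests on this generator
therefore shows the pipeline is correct and well calibrated for clean
monotone signals, not that real surveys will yield networks this crisp.

## Reference fixtures

A 19-site soil survey (1 humid, 6 semi-arid, 9 upper-arid, 3 lower-arid
Tunisian *Opuntia ficus-indica* plantations) ships as
`load_table2_fixture()`, stored exactly as printed — including a
physically impossible humid-site pH of 74.3 (certainly 7.43);
`corrected=True` substitutes 7.43 and records the change in
`DataFrame.attrs`.  `load_zone_fixture()` carries the site→zone map; one
boundary site (BA1) is printed ambiguously adjacent to the humid row in
the source layout and is assigned to its semi-arid site group.

## Numerical choices and degenerate inputs

* Rarefaction uses multivariate hypergeometric sampling (exact
  without-replacement); samples below depth are dropped and logged, and a
  sample exactly at depth passes through unchanged.
* ANOVA on identical values returns F = 0, p = 1 (rather than NaN);
  Tukey on constant data returns all pairwise p = 1; size-1 groups are
  excluded from Tukey with a warning.
* Trend r is clipped to [−1, 1]; zero-variance profiles get r = 0.
* BH with a single p-value is the identity; q ≥ p elementwise.
* Organelle matching is a case-insensitive substring scan
  ("chloroplast", "mitochondri") over every rank, since reference
  taxonomies place chloroplasts at class and mitochondria at family
  level.
* Taxonomy aggregation routes unassigned OTUs to an "Unclassified"
  bucket so per-sample totals are conserved to 1e-9.
* All randomness flows through numpy `default_rng`/`SeedSequence`;
  pipeline manifests carry no timestamps, so equal seeds give
  byte-identical artifacts.

## Problem sizes used in validation

The test suite and the acceptance script run the generator at its default
conditions (300 OTUs, 72 samples, depth 5000), the PERMANOVA calibration
at 200 replicates × 999 permutations on 16-sample communities, exhaustive
PERMANOVA at n = 6, and network oracles at ≤ 30 features — sizes at which
every check is exact or tightly concentrated while the whole validation
completes in well under a minute.

## Known limitations

* Plain Pearson/Spearman correlations on relative abundances inherit
  compositional bias (spurious negative correlation); the network is a
  faithful implementation of that screen, not a compositionality-aware
  association method.
* The trend rule is descriptive: it controls no error rate in zone-mean
  mode and makes no count-model assumptions; users wanting inference
  should pair it with a differential-abundance test.
* With a single humid site (as in the reference design) Tukey excludes
  the humid group and PERMANOVA by zone is not estimable within that
  zone; the pipeline degrades gracefully (warnings, skipped rows) rather
  than failing.
* BIOM support is read-only and covers the HDF5 CSR layout of BIOM 2.x.
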