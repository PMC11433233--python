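# Methods

This note records the model, the exact conventions implemented, the default
parameters and why they were chosen, and the limitations of the approach.

## 1. Data model

- **Taxonomy.** Seven ranks: phylum, class, order, family, genus, species,
  organism. Lineages are tuples; all rank comparisons in the package use
  lineage *prefixes*, never bare taxon names, so identically named taxa in
  different parents are distinct. Missing lower ranks in ingested data are
  filled with `unclassified_<parent>` placeholders (an empty phylum is an
  error); the fill is idempotent.
- **BGC.** A biosynthetic gene cluster carries a genome reference, a
  biosynthetic type (`T1PKS`, `NRPS`, `NRPS-like`, `terpene`, `T1PKS&NRPS`,
  `T1PKS&NRPS-like`, `other`), a positive length in kb, a sparse non-negative
  domain-weight map with at least one positive weight, and optionally the
  linear order of domains along the cluster.
- **Anchor.** A link from one BGC to a known compound and its natural-product
  (NP) cluster — a family of structurally related compounds. Anchors are the
  supervision used for threshold calibration and for annotating families.

## 2. Synthetic generator

The generator produces datasets in which every downstream quantity has a
known ground truth.

- **Taxonomy** is a deterministic balanced tree (default: 2 phyla, fanout 2
  at class/order/family/genus/species); genomes are assigned uniformly at
  random over species.
- **Archetypes** are the true gene cluster families. Each archetype has a
  domain-weight profile built from a *backbone* block (≈8% of the
  vocabulary, weights U(50,100)) shared by the archetypes of one NP family,
  plus an archetype-specific block (≈3% of the vocabulary, U(20,40)).
  Backbones therefore model the shared core enzymes that make members of a
  compound family look alike, and give the calibration problem its
  structure: after L2 normalization, archetypes of one family sit ≈0.3–0.35
  apart while different families sit ≥1.0 apart. A configurable fraction of
  archetypes are singletons with their own fresh backbone (their family is
  themselves).
- **Placement.** Each archetype is homed at a rank drawn from a distribution
  over {species … phylum, multi-phyla} (defaults 0.40/0.20/0.08/0.07/0.07/
  0.10/0.08) and at a uniformly chosen taxon of that rank; every genome in
  the home clade carries the archetype independently with the occupancy
  probability (default 0.6). Observed domain weights are the profile plus
  isotropic Gaussian noise (default sd 3.0) truncated at zero; the domain
  order is the archetype's canonical order restricted to positive weights.
- **Anchors** are drawn over realized archetypes (default fraction 0.3), one
  member BGC each; several archetypes of the same NP family may be anchored,
  which is exactly what makes ΔGCF informative at low thresholds.
- **Randomness** uses `numpy.random.SeedSequence([seed, stream])` with a
  distinct stream per stage, so changing one stage's draws cannot perturb
  another's, and a fixed seed reproduces every table byte for byte.
- **Ground truth** records BGC→archetype, archetype→NP family, and per-genus
  archetype richness (archetypes homed at or below the genus, plus realized
  singletons), which is the target of the pGCF recovery study.

What the generator does *not* emulate: gene-level synteny within clusters
beyond a fixed canonical domain order, horizontal transfer, genome
incompleteness/fragmentation, or unbalanced real-world taxon sampling.

## 3. Clustering

BGCs are embedded as L2-normalized domain-weight vectors over the shared
vocabulary, so Euclidean distances lie in [0, √2] and a threshold T is
scale-free. Clustering is two-pass nearest-centroid:

1. **Incremental pass** in ascending BGC id: each vector joins the nearest
   running-mean centroid if its distance is ≤ T, else founds a new family.
2. **Refinement pass**: centroids are frozen and every vector is reassigned
   to its nearest centroid (ties to the lowest family id); emptied families
   are dropped and ids re-densified.

The refinement makes membership order-invariant given the centroids; the
family count is monotonically non-increasing in T. Default T = 0.55.

## 4. Calibration

Anchored BGCs are clustered over a grid of thresholds (default 0.1–1.1,
step 0.05). For each T the partition is scored against the anchors' NP
clusters with the V-measure: homogeneity h = 1 − H(true|cluster)/H(true),
completeness symmetrically, v their harmonic mean (conditional entropies are
computed as H(joint) − H(marginal); degenerate zero-entropy marginals give
score 1 for the corresponding component). ΔGCF = n_families − n_NP-clusters
is stored signed; selection maximizes v, then minimizes |ΔGCF|, then T. A
warning is issued if no grid point clears v > 0.9. Calibration requires at
least two anchors spanning at least two NP clusters.

## 5. Diversity statistics

- **Incidence matrix**: GCF × genome boolean presence; genomes without BGCs
  appear as all-false columns so sampling effort is not silently inflated.
- **Specificity**: a GCF's class is the lowest rank whose lineage prefix is
  unanimous across carrier genomes: species-specific, genus-, family-,
  order-, class-, phylum-specific, else multi-phyla. GCFs with zero carriers
  are excluded with a warning.
- **GCF type**: modal member type, ties broken lexicographically.
- **Rank variance**: for each parent taxon at phylum…genus, the sample
  variance (ddof = 1) of distinct-GCF richness across its children; parents
  with fewer than two children are excluded; a Kruskal–Wallis test compares
  the variance distributions across ranks.
- **Per-phylum summary**: genomes, BGCs, GCFs, mean distinct GCFs per
  genome, and the count/share of GCFs containing an anchored member.

## 6. Rarefaction and extrapolation

From incidence frequencies (Q_j = number of GCFs found in exactly j of the
n sampling units):

- **Rarefaction** (t ≤ n): S(t) = S_obs − Σ_j Q_j · C(n−j, t)/C(n, t),
  evaluated with log-gamma binomials for numerical stability; verified in
  the tests against exhaustive averaging over all C(n, t) subsets.
- **Chao2**: S_obs + ((n−1)/n)·Q1²/(2Q2) when Q2 > 0, otherwise the
  bias-corrected S_obs + ((n−1)/n)·Q1(Q1−1)/2. Never below S_obs.
- **Extrapolation** (t* additional units): S_obs + Q̂0·[1 − (1 −
  Q1/(nQ̂0+Q1))^t*] with Q̂0 = Chao2 − S_obs; equals S_obs at t* = 0 and
  tends to Chao2 as t* → ∞.
- **Curves** run over 500 knots to a common endpoint of 10,000 genomes so
  genera with different sampling depths are comparable; pGCF is the curve's
  endpoint value. An endpoint below the sample size is raised to it with a
  warning.
- A genus is **promising** when its known NP-cluster count is strictly below
  10% of its pGCF.

## 7. Annotation, query search, network, census

- **Anchor linkage**: every member of a family containing an anchored BGC
  inherits the anchor's NP clusters; families with anchors from several NP
  clusters are flagged ambiguous.
- **Representatives**: one member per family, chosen uniformly from the
  sorted member list with a seeded generator.
- **Query search** (drug-similarity): a query cluster is a set of genes,
  each a domain set, some marked *core*. A gene matches a target BGC if some
  sliding window of the target's domain order (window length = the gene's
  domain count) has Jaccard ≥ 0.5 with the gene's domain set. A target is a
  hit when *all* core genes match and the matched gene fraction is ≥ 0.6.
  Hits found on representatives are expanded to all family members.
- **Similarity network** over hit BGCs: edge weight = 0.5·Jaccard(domain
  sets) + 0.5·adjacency index (shared unordered consecutive domain pairs);
  edges kept above a cutoff (default 0.5); connected components computed
  with networkx.
- **Census**: per query, hits are tallied by genus; the focal-genus share is
  reported against the genera with the highest pGCF.

## 8. Report arithmetic

Ratio statistics (known-family share, per-genus share, singleton-BGC share,
virtual families = pGCF − observed, type-within-genus share, drug focal
share, hit totals) are computed from a plain counts mapping. Printed
renderings use decimal half-up rounding at a per-statistic precision
(1 decimal for percentages, 2 for the singleton-BGC share, integers for
counts), via `Decimal(repr(x))` so binary-float ties round as a human would
round the printed value. Zero denominators drop the statistic with a
warning; negative counts are an error.

## 9. Default problem sizes and test design

Desk-scale defaults (300 genomes, 150 archetypes, 150-domain vocabulary)
run the full pipeline in under a second and keep every acceptance study
within minutes. Corpus-scale figures reported for real kingdom-wide surveys
(hundreds of thousands of BGCs) are out of scope by design.

Two stochastic studies fix their generator conditions a priori from the
model's structure rather than from observed outcomes:

- **pGCF recovery** needs each genus's archetypes to be observable:
  occupancy 0.8, no noise, no singletons, and a flatter taxonomy
  (fanout 1 at class/order) so each genus holds ~25 genomes. Under these
  conditions extrapolated richness matches true per-genus richness within
  15% (in practice exactly).
- **Rank-variance ordering** (genus variances below family variances) is
  only detectable when within-genus richness is homogeneous, so the test
  homes archetypes at genus level or above and raises occupancy to 0.9.

## 10. Limitations

- The clustering is a nearest-centroid heuristic, not a global optimum; at
  thresholds between the within-family and between-family distance scales
  results are stable, between regimes they can depend on insertion order
  (pass 2 bounds, but does not remove, this effect).
- Chao2 is a lower bound on true richness; extrapolation far beyond the
  observed sample size inherits its bias, and the common 10,000-genome
  endpoint is a convention, not a prediction.
- Query search requires domain orders; BGCs lacking them fall back to a
  sorted-domain pseudo-order, which weakens adjacency information.
- On noisy data a family representative may be a different archetype than a
  query's source, so zero hits for a hand-written query are possible and
  correct; self-consistent demonstrations should build queries from
  representative BGCs.
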