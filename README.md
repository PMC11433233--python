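# fungcf

Desk-scale analysis of natural-product biosynthetic diversity encoded in
fungal genomes: from biosynthetic gene clusters (BGCs) to gene cluster
families (GCFs), and from observed families to the extrapolated family
richness (pGCF) a genus would reveal under deeper genome sampling.

## What it does

A fungal genome typically encodes dozens of BGCs — co-located groups of
genes that together make one natural product. Clustering BGCs across many
genomes into GCFs (families of clusters that likely make the same or closely
related compounds) turns raw genome mining into a diversity survey: how many
distinct compound families does a genus encode, how taxonomically restricted
are they, how many are already linked to a known compound, and how much is
still unobserved?

`fungcf` implements that survey end to end:

- **Synthetic data generator** — a hierarchical taxonomy (phylum → …
  → species → genome) populated with BGC *archetypes*: protein-domain weight
  profiles homed at a taxonomic rank, grouped into compound families via
  shared backbone enzymes, and observed with per-genome occupancy and
  Gaussian measurement noise. Ground truth (archetype and compound-family
  membership, per-genus richness) is emitted alongside the data.
- **Feature vectors & threshold clustering** — L2-normalized domain-weight
  vectors; a two-pass nearest-centroid algorithm (incremental assignment
  followed by reassignment against frozen centroids) groups BGCs into GCFs
  at a distance threshold T.
- **Threshold calibration** — scans T over a grid, scoring the clustering of
  compound-anchored BGCs against their compound families with the V-measure
  (entropy-based homogeneity/completeness) and ΔGCF (family count minus
  compound-cluster count); picks the best-scoring T.
- **Diversity statistics** — GCF × genome incidence matrix; taxonomic
  specificity classes (species-specific up to multi-phyla, decided on
  lineage prefixes); modal biosynthetic type per GCF; type-by-range tables;
  per-phylum summaries; richness-variance-by-rank analysis with a
  Kruskal–Wallis test.
- **Rarefaction & extrapolation** — incidence-based rarefaction with an
  exact hypergeometric formula, the Chao2 richness estimator (bias-corrected
  when needed), and extrapolation to a common endpoint (default 10,000
  genomes) giving pGCF per genus; genera whose known-compound count falls
  below 10% of pGCF are flagged as promising.
- **Annotation & drug search** — anchor BGCs (links to known compounds)
  annotate entire GCFs; query clusters with required core genes are searched
  against family representatives via sliding-window domain Jaccard matching;
  hits form a similarity network (domain Jaccard + adjacency index) and a
  per-drug genus census.
- **Report** — derived ratio statistics (known-family share, singleton
  share, virtual families, …) with exact half-up rounded printed renderings.

## Quick start

Run the whole pipeline on synthetic data:

```sh
fungcf run-all --seed 7 --out out/
```

which writes tab-separated tables for every stage (`calibration.tsv`,
`gcf_assignments.tsv`, `specificity.tsv`, `pgcf.tsv`, `summary.tsv`, …).
With the default configuration (300 genomes, 150 archetypes) the summary
reads:

```
statistic            raw                 printed  unit
known_gcf_share      38.94736842105263   38.9     %
genus_gcf_share      21.05263157894737   21.1     %
singleton_bgc_share  4.273504273504273   4.27     %
virtual_gcfs         24.888888888888886  25       count
```

and the per-genus extrapolation table starts:

```
genus             n_genomes  s_obs  chao2               pgcf                np_count  promising
phy1_c1_o1_f1_g1  9          12     12.88888888888889   12.88888888888889   3         False
phy1_c1_o1_f1_g2  11         11     11.0                11.0                1         True
phy1_c1_o1_f2_g2  9          20     44.888888888888886  44.888888888888886  3         True
```

Library use mirrors the pipeline stages:

```python
from fungcf import (GeneratorConfig, generate_dataset, featurize_all,
                    cluster, calibrate, default_grid, incidence, curve)

dataset, truth = generate_dataset(GeneratorConfig(seed=7))
cal = calibrate(dataset, default_grid())       # pick T on anchored BGCs
gcfs = cluster(featurize_all(dataset), cal.chosen_t)
matrix = incidence(gcfs, dataset)
genomes = [t.genome_id for t in dataset.taxonomy]
print(curve(matrix, genomes).pgcf)             # extrapolated richness
```

Other CLI verbs: `fungcf generate`, `fungcf calibrate`, `fungcf cluster`,
`fungcf report --counts counts.tsv`, and `fungcf run-all --config run.yaml`
with a flat YAML key-value config (generator and run options mixed freely).

Real data can be ingested from the same tab-separated formats the generator
writes (`taxonomy.tsv`, `bgcs.tsv`, `anchors.tsv`, `vocabulary.txt`), and
domain weights can be imported from hmmscan `--domtblout` output
(`fungcf.io.import_domtblout`).

## Tests

```sh
python -m pytest -q tests/
```

The suite covers every module with hand-computed examples, independent
brute-force oracles (exhaustive subset rarefaction, entropy-based V-measure,
unanimity-scan specificity), and ground-truth recovery studies on the
generator.

## Documentation

See `docs/methods.md` for the modelling assumptions, the exact formulas and
conventions (clustering passes, V-measure, Chao2/extrapolation, specificity,
query matching), parameter defaults and their rationale, and known
limitations.
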