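"""Taxonomic decomposition of gene-cluster-family diversity.

Builds the GCF-by-genome incidence (presence/absence) matrix, classifies
each family by the narrowest taxonomic range covering all of its carrier
genomes (species-specific ... multi-phyla), types families by their modal
member BGC type, summarises diversity per phylum, and compares richness
heterogeneity across ranks via the variance of child richness under each
parent taxon.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import GCFAssignment
from .model import (
    RANKS,
    SPECIFICITY_CLASSES,
    AnchorRecord,
    Dataset,
    TaxonomyRecord,
    ValidationError,
)

# ranks eligible as specificity classes, narrowest first, with their
# lineage-prefix lengths (phylum..organism indexing)
_SPEC_RANKS = [
    ("species-specific", 6),
    ("genus-specific", 5),
    ("family-specific", 4),
    ("order-specific", 3),
    ("class-specific", 2),
    ("phylum-specific", 1),
]


@dataclass
class IncidenceMatrix:
    """Boolean GCF-by-genome presence table."""

    df: pd.DataFrame  # index: gcf_id (int), columns: genome_id (str), dtype bool

    @property
    def gcf_ids(self) -> list[int]:
        return list(self.df.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def row_sums(self) -> pd.Series:
        return self.df.sum(axis=1)

    @property
    def col_sums(self) -> pd.Series:
        return self.df.sum(axis=0)


def incidence(assignment: GCFAssignment, dataset: Dataset) -> IncidenceMatrix:
    """Presence of each family in each genome; genomes with no BGCs appear
    as all-false columns so sampling-unit counts stay honest."""
    genome_of = {b.bgc_id: b.genome_id for b in dataset.bgcs}
    genomes = [t.genome_id for t in dataset.taxonomy]
    genome_set = set(genomes)
    gcfs = sorted(assignment.centroids)
    mat = pd.DataFrame(False, index=gcfs, columns=genomes)
    for bgc_id, gcf in assignment.membership.items():
        g = genome_of.get(bgc_id)
        if g is None or g not in genome_set:
            raise ValidationError(f"{bgc_id}: genome not resolvable in taxonomy")
        mat.at[gcf, g] = True
    return IncidenceMatrix(df=mat)


@dataclass
class SpecificityProfile:
    """Per-GCF specificity class and per-genome class tallies."""

    gcf_class: dict[int, str]
    per_genome_counts: pd.DataFrame  # index genome_id, columns SPECIFICITY_CLASSES


def specificity(
    matrix: IncidenceMatrix, taxonomy: Sequence[TaxonomyRecord]
) -> SpecificityProfile:
    """Classify each family by the lowest rank at which all carrier genomes
    fall under a single taxon; carriers spanning phyla are multi-phyla.

    Taxa are identified by full lineage prefixes, so identically named
    placeholders under different parents never collapse.
    """
    lineages = {t.genome_id: t.lineage for t in taxonomy}
    missing = set(matrix.genome_ids) - set(lineages)
    if missing:
        raise ValidationError(f"genomes absent from taxonomy: {sorted(missing)[:5]}")
    gcf_class: dict[int, str] = {}
    values = matrix.df.to_numpy()
    genome_ids = matrix.genome_ids
    for ri, gcf in enumerate(matrix.gcf_ids):
        carriers = [genome_ids[ci] for ci in np.flatnonzero(values[ri])]
        if not carriers:
            warnings.warn(f"GCF {gcf} has no carrier genomes; excluded", stacklevel=2)
            continue
        cls = "multi-phyla"
        for name, k in _SPEC_RANKS:
            prefixes = {lineages[g][:k] for g in carriers}
            if len(prefixes) == 1:
                cls = name
                break
        gcf_class[gcf] = cls
    counts = pd.DataFrame(
        0, index=[t.genome_id for t in taxonomy], columns=list(SPECIFICITY_CLASSES)
    )
    for ri, gcf in enumerate(matrix.gcf_ids):
        if gcf not in gcf_class:
            continue
        cls = gcf_class[gcf]
        for ci in np.flatnonzero(values[ri]):
            counts.at[genome_ids[ci], cls] += 1
    return SpecificityProfile(gcf_class=gcf_class, per_genome_counts=counts)


def gcf_types(assignment: GCFAssignment, dataset: Dataset) -> dict[int, str]:
    """Family type = modal member BGC type; ties break lexicographically."""
    type_of = {b.bgc_id: b.bgc_type for b in dataset.bgcs}
    tallies: dict[int, Counter] = {}
    for bgc_id, gcf in assignment.membership.items():
        tallies.setdefault(gcf, Counter())[type_of[bgc_id]] += 1
    out: dict[int, str] = {}
    for gcf, counter in tallies.items():
        top = max(counter.values())
        out[gcf] = min(t for t, c in counter.items() if c == top)
    return out


def type_by_range_matrix(
    profile: SpecificityProfile, types: dict[int, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts (and row percentages) of GCF types within each specificity
    class."""
    type_names = sorted(set(types.values()))
    counts = pd.DataFrame(0, index=list(SPECIFICITY_CLASSES), columns=type_names)
    for gcf, cls in profile.gcf_class.items():
        counts.at[cls, types[gcf]] += 1
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    return counts, pct.fillna(0.0)


@dataclass
class RankVarianceTable:
    """Per-rank lists of child-richness variances plus a cross-rank test."""

    variances: dict[str, list[float]]  # parent rank -> variance per parent taxon
    statistic: Optional[float]
    pvalue: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (rank, i, v)
            for rank, vals in self.variances.items()
            for i, v in enumerate(vals)
        ]
        return pd.DataFrame(rows, columns=["rank", "parent_index", "variance"])


def _richness_by_prefix(
    matrix: IncidenceMatrix, lineages: dict[str, tuple[str, ...]], k: int
) -> dict[tuple[str, ...], int]:
    """Distinct-GCF richness of every taxon identified by a k-long prefix."""
    groups: dict[tuple[str, ...], list[str]] = {}
    for g in matrix.genome_ids:
        groups.setdefault(lineages[g][:k], []).append(g)
    out = {}
    for prefix, genomes in groups.items():
        out[prefix] = int(matrix.df[genomes].any(axis=1).sum())
    return out


def rank_variance(
    matrix: IncidenceMatrix, taxonomy: Sequence[TaxonomyRecord]
) -> RankVarianceTable:
    """For each parent rank phylum..genus, the sample variance of distinct-GCF
    richness across each parent's immediate children; parents with fewer than
    two children are excluded.  Ranks are compared with a Kruskal-Wallis test
    on the pooled variance values."""
    lineages = {t.genome_id: t.lineage for t in taxonomy}
    variances: dict[str, list[float]] = {}
    for parent_k, parent_rank in zip(range(1, 6), RANKS[:5]):
        child_rich = _richness_by_prefix(matrix, lineages, parent_k + 1)
        by_parent: dict[tuple[str, ...], list[int]] = {}
        for child_prefix, rich in child_rich.items():
            by_parent.setdefault(child_prefix[:parent_k], []).append(rich)
        vals = [
            float(np.var(r, ddof=1))
            for prefix, r in sorted(by_parent.items())
            if len(r) >= 2
        ]
        if not vals:
            warnings.warn(f"no parent at rank {parent_rank} has >= 2 children", stacklevel=2)
            continue
        variances[parent_rank] = vals
    groups = [v for v in variances.values() if len(v) >= 1]
    statistic = pvalue = None
    if len(groups) >= 2:
        try:
            statistic, pvalue = stats.kruskal(*groups)
            statistic, pvalue = float(statistic), float(pvalue)
        except ValueError:
            # all values identical across groups
            statistic, pvalue = None, None
    return RankVarianceTable(variances=variances, statistic=statistic, pvalue=pvalue)


def phylum_summary(
    matrix: IncidenceMatrix,
    taxonomy: Sequence[TaxonomyRecord],
    anchors: Sequence[AnchorRecord],
    assignment: GCFAssignment,
    dataset: Optional[Dataset] = None,
) -> pd.DataFrame:
    """Per-phylum genome/BGC/GCF counts, mean distinct GCFs per genome, and
    known GCFs (families containing an anchored BGC) with their share.

    BGC tallies need each BGC's genome, so they are filled from ``dataset``
    when it is supplied and reported as 0 otherwise.
    """
    phylum_of = {t.genome_id: t.lineage[0] for t in taxonomy}
    known_gcfs = {
        assignment.membership[a.bgc_id]
        for a in anchors
        if a.bgc_id in assignment.membership
    }
    bgc_per_phylum: Counter = Counter()
    if dataset is not None:
        for b in dataset.bgcs:
            bgc_per_phylum[phylum_of[b.genome_id]] += 1
    df = matrix.df
    phyla = sorted(set(phylum_of.values()))
    rows = []
    for ph in phyla:
        genomes = [g for g in df.columns if phylum_of[g] == ph]
        sub = df[genomes]
        present = sub.any(axis=1)
        n_gcfs = int(present.sum())
        per_genome = sub.sum(axis=0)
        known_here = sum(1 for g in df.index[present] if g in known_gcfs)
        rows.append(
            (
                ph,
                len(genomes),
                int(bgc_per_phylum.get(ph, 0)),
                n_gcfs,
                float(per_genome.mean()) if len(genomes) else 0.0,
                known_here,
                100.0 * known_here / n_gcfs if n_gcfs else 0.0,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "phylum",
            "n_genomes",
            "n_bgcs",
            "n_gcfs",
            "gcfs_per_genome",
            "known_gcfs",
            "known_pct",
        ],
    )
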