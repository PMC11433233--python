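"""Anchor-based annotation and the drug-similarity census.

Two complementary routes from known chemistry into the GCF landscape:

* **Anchors** — a family containing a BGC with a known compound inherits
  that compound's structural NP cluster, annotating every member BGC at once.
* **Query search** — a known drug's cluster (ordered genes, each a set of
  domains, some flagged as core) is matched against one representative BGC
  per family; core genes are required, and hits are expanded to all members
  of their families.  Hit BGCs are then re-clustered into a similarity
  network whose edge weight blends domain-content Jaccard with an adjacency
  index over consecutive domain pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .clustering import GCFAssignment
from .model import AnchorRecord, BGCRecord, Dataset, TaxonomyRecord, ValidationError


@dataclass
class QueryGene:
    domains: frozenset[str]
    core: bool


@dataclass
class QueryCluster:
    """A known cluster used as a homology-search query (e.g. a drug BGC)."""

    query_id: str
    genes: list[QueryGene]

    def __post_init__(self) -> None:
        if not any(g.core for g in self.genes):
            raise ValidationError(f"{self.query_id}: query needs >= 1 core gene")


@dataclass
class AnchorLinkage:
    gcf_to_np: dict[int, set[str]]
    annotated: list[tuple[str, int, str, bool]]  # bgc_id, gcf, np clusters, ambiguous
    n_known_gcfs: int
    n_annotated_bgcs: int


def link_anchors(assignment: GCFAssignment, anchors: Sequence[AnchorRecord]) -> AnchorLinkage:
    """Propagate each anchor's NP cluster to all members of its family."""
    gcf_to_np: dict[int, set[str]] = {}
    for a in anchors:
        if a.bgc_id not in assignment.membership:
            raise ValidationError(f"anchor to unassigned BGC {a.bgc_id}")
        gcf_to_np.setdefault(assignment.membership[a.bgc_id], set()).add(a.np_cluster_id)
    annotated = []
    for bgc_id in sorted(assignment.membership):
        gcf = assignment.membership[bgc_id]
        if gcf in gcf_to_np:
            nps = sorted(gcf_to_np[gcf])
            annotated.append((bgc_id, gcf, ";".join(nps), len(nps) > 1))
    return AnchorLinkage(
        gcf_to_np=gcf_to_np,
        annotated=annotated,
        n_known_gcfs=len(gcf_to_np),
        n_annotated_bgcs=len(annotated),
    )


def representatives(assignment: GCFAssignment, seed: int) -> dict[int, str]:
    """One uniformly chosen member BGC per family; deterministic per seed."""
    rng = np.random.default_rng(seed)
    reps: dict[int, str] = {}
    for gcf, members in sorted(assignment.members().items()):
        reps[gcf] = members[rng.integers(0, len(members))]
    return reps


def _domain_sequence(bgc: BGCRecord) -> tuple[str, ...]:
    if bgc.domain_order:
        return bgc.domain_order
    return tuple(sorted(bgc.domains))


def _gene_matches(gene: QueryGene, order: tuple[str, ...], jaccard_min: float) -> bool:
    k = len(gene.domains)
    if k == 0:
        return False
    if len(order) <= k:
        windows = [order]
    else:
        windows = [order[i : i + k] for i in range(len(order) - k + 1)]
    for w in windows:
        ws = set(w)
        inter = len(ws & gene.domains)
        union = len(ws | gene.domains)
        if union and inter / union >= jaccard_min:
            return True
    return False


def query_search(
    query: QueryCluster,
    reps: Mapping[int, str],
    dataset: Dataset,
    min_gene_frac: float = 0.6,
    gene_jaccard: float = 0.5,
    assignment: Optional[GCFAssignment] = None,
) -> list[str]:
    """Core-gene-required search of a query cluster over representatives.

    A representative is a hit iff every core query gene matches somewhere in
    its domain order (a gene matches when some sliding window of the gene's
    size reaches Jaccard >= ``gene_jaccard`` against the gene's domain set)
    and the fraction of all query genes matched is >= ``min_gene_frac``.
    When ``assignment`` is given, hits are expanded to all members of the hit
    representatives' families; otherwise the representative ids are returned.
    """
    if not 0 <= min_gene_frac <= 1:
        raise ValidationError("min_gene_frac must lie in [0, 1]")
    if not any(g.core for g in query.genes):
        raise ValidationError(f"{query.query_id}: no core genes")
    bgc_index = dataset.bgc_index
    hit_gcfs: list[int] = []
    for gcf in sorted(reps):
        bgc = bgc_index[reps[gcf]]
        order = _domain_sequence(bgc)
        matched = [_gene_matches(g, order, gene_jaccard) for g in query.genes]
        core_ok = all(m for g, m in zip(query.genes, matched) if g.core)
        frac_ok = sum(matched) / len(query.genes) >= min_gene_frac
        if core_ok and frac_ok:
            hit_gcfs.append(gcf)
    if assignment is None:
        return [reps[g] for g in hit_gcfs]
    members = assignment.members()
    hits: list[str] = []
    for g in hit_gcfs:
        hits.extend(members[g])
    return sorted(hits)


@dataclass
class SimilarityNetwork:
    graph: nx.Graph
    cutoff: float
    components: list[set[str]]


def _adjacent_pairs(order: tuple[str, ...]) -> set[frozenset[str]]:
    return {frozenset((a, b)) for a, b in zip(order, order[1:]) if a != b}


def pairwise_similarity(a: BGCRecord, b: BGCRecord) -> float:
    """0.5 * Jaccard of domain sets + 0.5 * adjacency index over unordered
    consecutive domain pairs (0 when both clusters have < 2 domains)."""
    sa, sb = set(_domain_sequence(a)), set(_domain_sequence(b))
    union = sa | sb
    jaccard = len(sa & sb) / len(union) if union else 0.0
    pa, pb = _adjacent_pairs(_domain_sequence(a)), _adjacent_pairs(_domain_sequence(b))
    if len(_domain_sequence(a)) < 2 and len(_domain_sequence(b)) < 2:
        adjacency = 0.0
    else:
        pu = pa | pb
        adjacency = len(pa & pb) / len(pu) if pu else 0.0
    return 0.5 * jaccard + 0.5 * adjacency


def network(
    bgcs: Sequence[BGCRecord],
    cutoff: float,
    taxonomy: Optional[Sequence[TaxonomyRecord]] = None,
    drug_of: Optional[Mapping[str, str]] = None,
) -> SimilarityNetwork:
    """Similarity network over hit BGCs; edges kept at similarity >= cutoff."""
    if not bgcs:
        raise ValidationError("network needs >= 1 BGC")
    if not 0 <= cutoff <= 1:
        raise ValidationError("cutoff must lie in [0, 1]")
    genus_of = {}
    if taxonomy is not None:
        genus_of = {t.genome_id: t.taxon("genus") for t in taxonomy}
    g = nx.Graph()
    for b in bgcs:
        g.add_node(
            b.bgc_id,
            genus=genus_of.get(b.genome_id, ""),
            drug=(drug_of or {}).get(b.bgc_id, ""),
        )
    ordered = sorted(bgcs, key=lambda b: b.bgc_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            s = pairwise_similarity(a, b)
            if s >= cutoff:
                g.add_edge(a.bgc_id, b.bgc_id, weight=s)
    components = [set(c) for c in nx.connected_components(g)]
    return SimilarityNetwork(graph=g, cutoff=cutoff, components=components)


@dataclass
class CensusRow:
    query_id: str
    total_hits: int
    genus_counts: dict[str, int]
    focal_hits: int
    focal_pct: float


def drug_census(
    hits_per_query: Mapping[str, Sequence[str]],
    dataset: Dataset,
    focal_genera: Sequence[str],
) -> list[CensusRow]:
    """Per-drug tally of hit BGCs, their genus breakdown, and the share of
    hits falling in the focal (top-diversity) genera."""
    genus_of_genome = {t.genome_id: t.taxon("genus") for t in dataset.taxonomy}
    genome_of = {b.bgc_id: b.genome_id for b in dataset.bgcs}
    focal = set(focal_genera)
    rows = []
    for query_id in sorted(hits_per_query):
        hits = hits_per_query[query_id]
        genera = Counter(genus_of_genome[genome_of[h]] for h in hits)
        focal_hits = sum(c for g, c in genera.items() if g in focal)
        total = len(hits)
        rows.append(
            CensusRow(
                query_id=query_id,
                total_hits=total,
                genus_counts=dict(sorted(genera.items())),
                focal_hits=focal_hits,
                focal_pct=100.0 * focal_hits / total if total else 0.0,
            )
        )
    return rows


def read_query_file(path) -> list[QueryCluster]:
    """Read queries from a TSV with columns query_id, gene_index, core,
    domains (comma-separated)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"query_id", "gene_index", "core", "domains"}
    if not required <= set(df.columns):
        raise ValidationError(f"query file missing columns {sorted(required - set(df.columns))}")
    queries: dict[str, list[tuple[int, QueryGene]]] = {}
    for row in df.itertuples(index=False):
        gene = QueryGene(
            domains=frozenset(d for d in str(row.domains).split(",") if d),
            core=str(row.core).strip().lower() in ("1", "true", "yes"),
        )
        queries.setdefault(str(row.query_id), []).append((int(row.gene_index), gene))
    out = []
    for qid in sorted(queries):
        genes = [g for _, g in sorted(queries[qid], key=lambda x: x[0])]
        out.append(QueryCluster(query_id=qid, genes=genes))
    return out
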