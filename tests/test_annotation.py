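"""Anchor linking, representatives, core-gene query search, similarity
network and the drug census."""

import numpy as np
import pytest

from fungcf.annotation import (
    QueryCluster,
    QueryGene,
    drug_census,
    link_anchors,
    network,
    pairwise_similarity,
    query_search,
    read_query_file,
    representatives,
)
from fungcf.clustering import GCFAssignment
from fungcf.model import AnchorRecord, ValidationError
from tests.conftest import make_bgc


def assignment_of(mapping):
    centroids = {g: np.zeros(2) for g in set(mapping.values())}
    return GCFAssignment(threshold=0.5, membership=dict(mapping), centroids=centroids)


class TestLinkAnchors:
    def test_annotation_inherited_by_all_members(self):
        a = assignment_of({f"b{i}": 0 for i in range(5)})
        linkage = link_anchors(a, [AnchorRecord("b0", "c", "np1")])
        assert linkage.n_annotated_bgcs == 5
        assert linkage.n_known_gcfs == 1

    def test_no_anchors_empty(self):
        a = assignment_of({"b0": 0})
        linkage = link_anchors(a, [])
        assert linkage.gcf_to_np == {}

    def test_conflicting_np_clusters_flagged_ambiguous(self):
        a = assignment_of({"b0": 0, "b1": 0})
        linkage = link_anchors(
            a, [AnchorRecord("b0", "c1", "np1"), AnchorRecord("b1", "c2", "np2")]
        )
        assert all(amb for _, _, _, amb in linkage.annotated)

    def test_conservation_over_linked_families(self):
        a = assignment_of({"b0": 0, "b1": 0, "b2": 1, "b3": 2})
        linkage = link_anchors(a, [AnchorRecord("b0", "c", "np1"), AnchorRecord("b2", "c2", "np2")])
        sizes = a.sizes()
        assert linkage.n_annotated_bgcs == sum(sizes[g] for g in linkage.gcf_to_np)

    def test_anchor_to_unassigned_bgc_rejected(self):
        a = assignment_of({"b0": 0})
        with pytest.raises(ValidationError):
            link_anchors(a, [AnchorRecord("zz", "c", "np1")])


class TestRepresentatives:
    def test_singleton_family_returns_only_member(self):
        a = assignment_of({"b0": 0})
        assert representatives(a, 1)[0] == "b0"

    def test_deterministic_per_seed(self):
        a = assignment_of({f"b{i}": i % 3 for i in range(12)})
        assert representatives(a, 5) == representatives(a, 5)

    def test_representative_is_member(self):
        a = assignment_of({f"b{i}": i % 3 for i in range(12)})
        members = a.members()
        for gcf, rep in representatives(a, 7).items():
            assert rep in members[gcf]


def dataset_with_orders(orders, toy):
    """Replace toy_dataset's BGCs with ones having the given domain orders."""
    from fungcf.model import Dataset

    vocab = sorted({d for o in orders.values() for d in o})
    bgcs = [
        make_bgc(b, "g1", {d: 1.0 for d in o}, order=o) for b, o in sorted(orders.items())
    ]
    return Dataset(taxonomy=toy.taxonomy, bgcs=bgcs, anchors=[], domain_vocabulary=tuple(vocab))


class TestQuerySearch:
    def query_from(self, order, core_genes=1, gene_size=2):
        genes = [
            QueryGene(frozenset(order[i : i + gene_size]), i // gene_size < core_genes)
            for i in range(0, len(order), gene_size)
        ]
        return QueryCluster(query_id="q", genes=genes)

    def test_identical_target_hits(self, toy_dataset):
        order = ("x1", "x2", "x3", "x4")
        ds = dataset_with_orders({"b1": order}, toy_dataset)
        q = self.query_from(order)
        hits = query_search(q, {0: "b1"}, ds)
        assert hits == ["b1"]

    def test_missing_core_gene_is_fatal(self, toy_dataset):
        ds = dataset_with_orders({"b1": ("y1", "y2", "y3", "y4")}, toy_dataset)
        q = self.query_from(("x1", "x2", "y3", "y4"))  # core gene (x1,x2) absent
        assert query_search(q, {0: "b1"}, ds) == []

    def test_gene_fraction_rule(self, toy_dataset):
        # 3 genes (2 core); target carries only the two core genes: 2/3 >= 0.6
        order = ("c1", "c2", "c3", "c4", "e1", "e2")
        genes = [
            QueryGene(frozenset(("c1", "c2")), True),
            QueryGene(frozenset(("c3", "c4")), True),
            QueryGene(frozenset(("zz1", "zz2")), False),
        ]
        q = QueryCluster("q", genes)
        ds = dataset_with_orders({"b1": ("c1", "c2", "c3", "c4")}, toy_dataset)
        assert query_search(q, {0: "b1"}, ds, min_gene_frac=0.6) == ["b1"]
        assert query_search(q, {0: "b1"}, ds, min_gene_frac=0.7) == []

    def test_hits_expand_to_family_members(self, toy_dataset):
        order = ("x1", "x2", "x3", "x4")
        ds = dataset_with_orders({"b1": order, "b2": order, "b3": ("z1",)}, toy_dataset)
        a = assignment_of({"b1": 0, "b2": 0, "b3": 1})
        q = self.query_from(order)
        hits = query_search(q, {0: "b1", 1: "b3"}, ds, assignment=a)
        assert hits == ["b1", "b2"]

    def test_query_without_core_genes_rejected(self):
        with pytest.raises(ValidationError):
            QueryCluster("q", [QueryGene(frozenset(("a",)), False)])

    def test_self_hit_when_query_built_from_representative(self, small_dataset):
        from fungcf.clustering import cluster, featurize_all

        dataset, _ = small_dataset
        a = cluster(featurize_all(dataset), 0.55)
        reps = representatives(a, 3)
        gcf, rep = sorted(reps.items())[0]
        bgc = dataset.bgc_index[rep]
        order = bgc.domain_order
        genes = [
            QueryGene(frozenset(order[i : i + 3]), i == 0)
            for i in range(0, min(9, len(order)), 3)
        ]
        q = QueryCluster("self", genes)
        hits = query_search(q, reps, dataset, assignment=a)
        assert rep in hits


class TestNetwork:
    def test_identical_orders_similarity_one(self, toy_dataset):
        ds = dataset_with_orders({"b1": ("a", "b", "c"), "b2": ("a", "b", "c")}, toy_dataset)
        assert pairwise_similarity(ds.bgcs[0], ds.bgcs[1]) == pytest.approx(1.0)

    def test_disjoint_orders_similarity_zero(self, toy_dataset):
        ds = dataset_with_orders({"b1": ("a", "b"), "b2": ("c", "d")}, toy_dataset)
        assert pairwise_similarity(ds.bgcs[0], ds.bgcs[1]) == 0.0

    def test_hand_computed_mixed_similarity(self, toy_dataset):
        # sets {A,B,C} vs {A,B,D}: Jaccard 2/4; pairs {AB,BC} vs {AB,BD}: 1/3
        ds = dataset_with_orders({"b1": ("A", "B", "C"), "b2": ("A", "B", "D")}, toy_dataset)
        sim = pairwise_similarity(ds.bgcs[0], ds.bgcs[1])
        assert sim == pytest.approx(0.5 * 0.5 + 0.5 / 3)

    def test_symmetry_and_bounds(self, small_dataset):
        dataset, _ = small_dataset
        rng = np.random.default_rng(0)
        picks = rng.choice(len(dataset.bgcs), size=12, replace=False)
        for i in picks[:6]:
            for j in picks[6:]:
                a, b = dataset.bgcs[int(i)], dataset.bgcs[int(j)]
                s1 = pairwise_similarity(a, b)
                assert 0.0 <= s1 <= 1.0
                assert s1 == pytest.approx(pairwise_similarity(b, a))

    def test_zero_cutoff_single_component_on_connected_support(self, toy_dataset):
        ds = dataset_with_orders(
            {"b1": ("a", "b"), "b2": ("b", "c"), "b3": ("c", "d")}, toy_dataset
        )
        net = network(ds.bgcs, 0.0)
        assert len(net.components) == 1

    def test_edges_respect_cutoff(self, toy_dataset):
        ds = dataset_with_orders({"b1": ("a", "b"), "b2": ("a", "b"), "b3": ("x", "y")}, toy_dataset)
        net = network(ds.bgcs, 0.9)
        assert set(net.graph.edges) == {("b1", "b2")}
        assert len(net.components) == 2


class TestDrugCensus:
    def test_totals_and_focal_share(self, toy_dataset):
        # hits resolved through toy genomes: g1,g2 in GenA; g3 in GenB
        hits = {"drug1": ["b1", "b2", "b3"]}
        rows = drug_census(hits, toy_dataset, focal_genera=["GenA"])
        assert rows[0].total_hits == 3
        assert rows[0].genus_counts == {"GenA": 2, "GenB": 1}
        assert rows[0].focal_hits == 2
        assert rows[0].focal_pct == pytest.approx(100 * 2 / 3)

    def test_empty_hits_zero_row(self, toy_dataset):
        rows = drug_census({"drug1": []}, toy_dataset, focal_genera=[])
        assert rows[0].total_hits == 0
        assert rows[0].focal_pct == 0.0


class TestQueryFile:
    def test_roundtrip_parse(self, tmp_path):
        p = tmp_path / "queries.tsv"
        p.write_text(
            "query_id\tgene_index\tcore\tdomains\n"
            "penicillin\t1\t0\td3,d4\n"
            "penicillin\t0\t1\td1,d2\n"
        )
        queries = read_query_file(p)
        assert len(queries) == 1
        q = queries[0]
        assert q.genes[0].core and q.genes[0].domains == {"d1", "d2"}
        assert not q.genes[1].core
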