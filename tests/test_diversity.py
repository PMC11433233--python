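"""Incidence matrix, specificity classification, typing, per-phylum
summaries and rank-variance analysis."""

import numpy as np
import pandas as pd
import pytest

from fungcf.clustering import GCFAssignment, cluster, featurize_all
from fungcf.diversity import (
    IncidenceMatrix,
    gcf_types,
    incidence,
    phylum_summary,
    rank_variance,
    specificity,
    type_by_range_matrix,
)
from fungcf.model import SPECIFICITY_CLASSES
from fungcf.simulate import GeneratorConfig, generate_dataset
from tests.conftest import make_bgc, make_taxonomy


def assignment_of(mapping):
    centroids = {g: np.zeros(2) for g in set(mapping.values())}
    return GCFAssignment(threshold=0.5, membership=dict(mapping), centroids=centroids)


class TestIncidence:
    def test_presence_rows(self, toy_dataset):
        a = assignment_of({"b1": 0, "b2": 0, "b3": 1, "b4": 1})
        m = incidence(a, toy_dataset)
        assert m.df.loc[0].tolist() == [True, True, False]
        assert m.df.loc[1].tolist() == [True, False, True]

    def test_multiple_bgcs_same_genome_idempotent(self, toy_dataset):
        a = assignment_of({"b1": 0, "b2": 1, "b3": 1, "b4": 0})
        m = incidence(a, toy_dataset)
        # b1 and b4 are both in g1 and both map to GCF 0: one true cell
        assert int(m.df.loc[0].sum()) == 1

    def test_bgc_free_genome_is_all_false_column(self, toy_dataset):
        toy_dataset.taxonomy.append(make_taxonomy("g4", genus="GenC", species="SpC1"))
        a = assignment_of({"b1": 0, "b2": 0, "b3": 1, "b4": 1})
        m = incidence(a, toy_dataset)
        assert int(m.df["g4"].sum()) == 0


def brute_force_class(lineages):
    """Oracle: scan ranks from species upward for a unanimous taxon."""
    for cls, k in [
        ("species-specific", 6),
        ("genus-specific", 5),
        ("family-specific", 4),
        ("order-specific", 3),
        ("class-specific", 2),
        ("phylum-specific", 1),
    ]:
        if len({l[:k] for l in lineages}) == 1:
            return cls
    return "multi-phyla"


class TestSpecificity:
    def test_basic_classes(self):
        taxonomy = [
            make_taxonomy("g1", phylum="P1", genus="GenA", species="Sp1"),
            make_taxonomy("g2", phylum="P1", genus="GenA", species="Sp1"),
            make_taxonomy("g3", phylum="P1", genus="GenA", species="Sp2"),
            make_taxonomy("g4", phylum="P2", cls="C2", genus="GenB", species="Sp3"),
        ]
        df = pd.DataFrame(
            [
                [True, True, False, False],   # both in Sp1 -> species-specific
                [True, False, True, False],   # two species, one genus -> genus-specific
                [True, False, False, True],   # spans phyla -> multi-phyla
            ],
            index=[0, 1, 2],
            columns=["g1", "g2", "g3", "g4"],
        )
        prof = specificity(IncidenceMatrix(df), taxonomy)
        assert prof.gcf_class == {
            0: "species-specific",
            1: "genus-specific",
            2: "multi-phyla",
        }

    def test_conservation_per_genome(self, small_dataset):
        dataset, _ = small_dataset
        a = cluster(featurize_all(dataset), 0.55)
        m = incidence(a, dataset)
        prof = specificity(m, dataset.taxonomy)
        richness = m.col_sums
        assert (prof.per_genome_counts.sum(axis=1) == richness).all()

    def test_agrees_with_brute_force_scan(self, small_dataset):
        dataset, _ = small_dataset
        a = cluster(featurize_all(dataset), 0.55)
        m = incidence(a, dataset)
        prof = specificity(m, dataset.taxonomy)
        lineages = {t.genome_id: t.lineage for t in dataset.taxonomy}
        vals = m.df.to_numpy()
        for ri, gcf in enumerate(m.gcf_ids):
            carriers = [m.genome_ids[ci] for ci in np.flatnonzero(vals[ri])]
            assert prof.gcf_class[gcf] == brute_force_class([lineages[g] for g in carriers])

    def test_adding_carrier_never_narrows_class(self):
        taxonomy = [
            make_taxonomy("g1", genus="GenA", species="Sp1"),
            make_taxonomy("g2", genus="GenA", species="Sp2"),
            make_taxonomy("g3", genus="GenB", species="Sp3"),
        ]
        order = list(SPECIFICITY_CLASSES)
        base = pd.DataFrame([[True, False, False]], index=[0], columns=["g1", "g2", "g3"])
        cls0 = specificity(IncidenceMatrix(base), taxonomy).gcf_class[0]
        for extra in ("g2", "g3"):
            wider = base.copy()
            wider.loc[0, extra] = True
            cls1 = specificity(IncidenceMatrix(wider), taxonomy).gcf_class[0]
            assert order.index(cls1) >= order.index(cls0)


class TestTypes:
    def test_modal_type(self, toy_dataset):
        a = assignment_of({"b1": 0, "b2": 0, "b3": 0, "b4": 1})
        types = gcf_types(a, toy_dataset)
        assert types[0] == "T1PKS"  # 2x T1PKS vs 1x NRPS

    def test_tie_breaks_lexicographically(self, toy_dataset):
        a = assignment_of({"b1": 0, "b3": 0, "b2": 1, "b4": 1})
        types = gcf_types(a, toy_dataset)
        assert types[0] == "NRPS"  # T1PKS vs NRPS tie

    def test_singleton_family_inherits_type(self, toy_dataset):
        a = assignment_of({"b1": 0, "b2": 1, "b3": 2, "b4": 3})
        assert gcf_types(a, toy_dataset)[2] == "NRPS"


class TestTypeByRange:
    def test_counts_and_percentages(self, toy_dataset):
        a = assignment_of({"b1": 0, "b2": 0, "b3": 1, "b4": 1})
        m = incidence(a, toy_dataset)
        prof = specificity(m, toy_dataset.taxonomy)
        counts, pct = type_by_range_matrix(prof, gcf_types(a, toy_dataset))
        assert counts.to_numpy().sum() == len(prof.gcf_class)
        nonzero = counts.sum(axis=1) > 0
        assert (pct[nonzero].sum(axis=1) - 100).abs().max() < 1e-9


class TestRankVariance:
    def test_closed_form_variances(self):
        # one phylum, one genus with 2 species of richness 2 and 4
        taxonomy = [
            make_taxonomy("g1", genus="GenA", species="Sp1"),
            make_taxonomy("g2", genus="GenA", species="Sp2"),
        ]
        df = pd.DataFrame(
            [
                [True, True],
                [True, True],
                [False, True],
                [False, True],
            ],
            index=[0, 1, 2, 3],
            columns=["g1", "g2"],
        )
        table = rank_variance(IncidenceMatrix(df), taxonomy)
        assert table.variances["genus"] == [pytest.approx(2.0)]

    def test_equal_children_give_zero_variance(self):
        taxonomy = [
            make_taxonomy(f"g{i}", genus="GenA", species=f"Sp{i}") for i in range(3)
        ]
        df = pd.DataFrame(
            [[True, True, True]] * 5, index=range(5), columns=[f"g{i}" for i in range(3)]
        )
        table = rank_variance(IncidenceMatrix(df), taxonomy)
        assert table.variances["genus"] == [pytest.approx(0.0)]

    def test_genus_variance_below_family_variance_on_homogeneous_genera(self):
        """When archetypes are homed at genus level or above, richness is
        homogeneous within genera, so genus-level variances sit stochastically
        below family-level ones."""
        genus_means, family_means = [], []
        probs = {
            "species": 0.0, "genus": 0.5, "family": 0.15, "order": 0.1,
            "class": 0.05, "phylum": 0.1, "multi-phyla": 0.1,
        }
        for seed in range(20):
            cfg = GeneratorConfig(
                seed=seed, n_genomes=200, n_archetypes=120, vocab_size=120,
                singleton_fraction=0.0, occupancy_prob=0.9, rank_probs=probs,
            )
            dataset, _ = generate_dataset(cfg)
            a = cluster(featurize_all(dataset), 0.3)
            m = incidence(a, dataset)
            table = rank_variance(m, dataset.taxonomy)
            genus_means.append(np.mean(table.variances["genus"]))
            family_means.append(np.mean(table.variances["family"]))
        assert np.mean(genus_means) < np.mean(family_means)
        wins = sum(g < f for g, f in zip(genus_means, family_means))
        assert wins >= 13  # stochastically below, not merely on average


class TestPhylumSummary:
    def test_counts_and_known_fraction(self, toy_dataset):
        a = assignment_of({"b1": 0, "b2": 0, "b3": 1, "b4": 2})
        m = incidence(a, toy_dataset)
        df = phylum_summary(m, toy_dataset.taxonomy, toy_dataset.anchors, a, toy_dataset)
        row = df[df.phylum == "Asco"].iloc[0]
        assert row.n_genomes == 3
        assert row.n_bgcs == 4
        assert row.n_gcfs == 3
        # per-genome distinct GCFs: g1 has {0,2}, g2 {0}, g3 {1}
        assert row.gcfs_per_genome == pytest.approx((2 + 1 + 1) / 3)
        assert row.known_gcfs == 2  # anchors b1 (GCF 0) and b3 (GCF 1)
        assert row.known_pct == pytest.approx(100 * 2 / 3)

    def test_no_anchor_phylum_reports_zero(self, toy_dataset):
        a = assignment_of({"b1": 0, "b2": 0, "b3": 1, "b4": 2})
        m = incidence(a, toy_dataset)
        df = phylum_summary(m, toy_dataset.taxonomy, [], a, toy_dataset)
        assert df.known_gcfs.tolist() == [0]
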