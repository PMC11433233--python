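import numpy as np
import pytest

from fungcf.model import AnchorRecord, BGCRecord, Dataset, TaxonomyRecord
from fungcf.simulate import GeneratorConfig, generate_dataset


def make_taxonomy(genome_id, phylum="Asco", cls="C1", order="O1", family="F1",
                  genus="G1", species="S1", organism=None):
    organism = organism or f"{species}_{genome_id}"
    return TaxonomyRecord(genome_id, (phylum, cls, order, family, genus, species, organism))


def make_bgc(bgc_id, genome_id, domains, bgc_type="T1PKS", length_kb=10.0, order=None):
    return BGCRecord(bgc_id, genome_id, bgc_type, length_kb, dict(domains),
                     tuple(order) if order else None)


@pytest.fixture
def toy_dataset():
    """3 genomes in 2 genera of one phylum, 4 BGCs in 2 natural families."""
    taxonomy = [
        make_taxonomy("g1", genus="GenA", species="SpA1"),
        make_taxonomy("g2", genus="GenA", species="SpA2"),
        make_taxonomy("g3", genus="GenB", species="SpB1"),
    ]
    bgcs = [
        make_bgc("b1", "g1", {"d1": 3.0, "d2": 4.0}, order=("d1", "d2")),
        make_bgc("b2", "g2", {"d1": 3.0, "d2": 4.0}, order=("d1", "d2")),
        make_bgc("b3", "g3", {"d3": 1.0}, bgc_type="NRPS", order=("d3",)),
        make_bgc("b4", "g1", {"d3": 1.0, "d4": 0.1}, bgc_type="NRPS", order=("d3", "d4")),
    ]
    anchors = [AnchorRecord("b1", "cpd1", "np1"), AnchorRecord("b3", "cpd2", "np2")]
    return Dataset(taxonomy=taxonomy, bgcs=bgcs, anchors=anchors,
                   domain_vocabulary=("d1", "d2", "d3", "d4"))


@pytest.fixture
def small_config():
    """A quick-to-generate synthetic corpus configuration."""
    return GeneratorConfig(seed=11, n_genomes=60, n_archetypes=40, vocab_size=80)


@pytest.fixture
def small_dataset(small_config):
    return generate_dataset(small_config)
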