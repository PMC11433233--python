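"""Core domain types shared by every stage of the pipeline.

The unit of analysis is the biosynthetic gene cluster (BGC): a set of
co-located genes encoding the biosynthesis of a secondary metabolite,
summarised here by its protein-domain composition.  BGCs are grouped into
gene cluster families (GCFs), the working measure of biosynthetic
diversity, and a subset of BGCs carries "anchor" links to known natural
products (compounds grouped into structural NP clusters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

#: Taxonomic ranks carried by every genome, highest to lowest.
RANKS: tuple[str, ...] = (
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "organism",
)

#: Canonical BGC type labels (core biosynthetic enzyme classes).
BGC_TYPES: tuple[str, ...] = (
    "T1PKS",
    "NRPS",
    "NRPS-like",
    "terpene",
    "T1PKS&NRPS",
    "T1PKS&NRPS-like",
    "other",
)

#: Specificity classes, narrowest to widest taxonomic range.
SPECIFICITY_CLASSES: tuple[str, ...] = (
    "species-specific",
    "genus-specific",
    "family-specific",
    "order-specific",
    "class-specific",
    "phylum-specific",
    "multi-phyla",
)


class ValidationError(ValueError):
    """Raised when a record or dataset violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an input file does not follow the expected layout."""


@dataclass(frozen=True)
class TaxonomyRecord:
    """A genome with its complete 7-rank lineage (phylum .. organism)."""

    genome_id: str
    lineage: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS):
            raise ValidationError(
                f"{self.genome_id}: lineage must have {len(RANKS)} ranks, "
                f"got {len(self.lineage)}"
            )
        if any(not t for t in self.lineage):
            raise ValidationError(f"{self.genome_id}: empty taxon in lineage")

    def taxon(self, rank: str) -> str:
        return self.lineage[RANKS.index(rank)]

    def prefix(self, rank: str) -> tuple[str, ...]:
        """Lineage truncated at ``rank`` (inclusive); identifies the taxon
        unambiguously even when bare names repeat under different parents."""
        return self.lineage[: RANKS.index(rank) + 1]


@dataclass
class BGCRecord:
    """One predicted biosynthetic gene cluster.

    ``domains`` maps protein-domain names to non-negative weights
    (bitscore-like evidence); ``domain_order`` optionally lists domains in
    genomic order along the cluster and may contain repeats.
    """

    bgc_id: str
    genome_id: str
    bgc_type: str
    length_kb: float
    domains: dict[str, float]
    domain_order: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.length_kb <= 0:
            raise ValidationError(f"{self.bgc_id}: length_kb must be > 0")
        if not self.domains:
            raise ValidationError(f"{self.bgc_id}: empty domain vector")
        if any(w < 0 for w in self.domains.values()):
            raise ValidationError(f"{self.bgc_id}: negative domain weight")
        if not any(w > 0 for w in self.domains.values()):
            raise ValidationError(f"{self.bgc_id}: all-zero domain vector")
        if self.domain_order is not None:
            self.domain_order = tuple(self.domain_order)


@dataclass(frozen=True)
class AnchorRecord:
    """Link from a BGC to a known compound and its structural NP cluster."""

    bgc_id: str
    compound_id: str
    np_cluster_id: str

    def __post_init__(self) -> None:
        if not self.np_cluster_id:
            raise ValidationError(f"anchor {self.bgc_id}: empty np_cluster_id")


@dataclass
class Dataset:
    """A complete input corpus: taxonomy, BGCs, anchors and the domain
    vocabulary over which feature vectors are laid out."""

    taxonomy: list[TaxonomyRecord]
    bgcs: list[BGCRecord]
    anchors: list[AnchorRecord]
    domain_vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.taxonomy:
            if rec.genome_id in seen:
                raise ValidationError(f"duplicate genome_id {rec.genome_id}")
            seen.add(rec.genome_id)
        genome_ids = seen
        bgc_ids: set[str] = set()
        vocab = set(self.domain_vocabulary)
        for bgc in self.bgcs:
            if bgc.bgc_id in bgc_ids:
                raise ValidationError(f"duplicate bgc_id {bgc.bgc_id}")
            bgc_ids.add(bgc.bgc_id)
            if bgc.genome_id not in genome_ids:
                raise ValidationError(
                    f"{bgc.bgc_id}: unknown genome {bgc.genome_id}"
                )
            missing = set(bgc.domains) - vocab
            if missing:
                raise ValidationError(
                    f"{bgc.bgc_id}: domains outside vocabulary: {sorted(missing)}"
                )
        anchored: set[str] = set()
        for a in self.anchors:
            if a.bgc_id in anchored:
                raise ValidationError(f"duplicate anchor for {a.bgc_id}")
            anchored.add(a.bgc_id)
            if a.bgc_id not in bgc_ids:
                raise ValidationError(f"anchor to unknown BGC {a.bgc_id}")

    @property
    def genome_index(self) -> dict[str, TaxonomyRecord]:
        return {t.genome_id: t for t in self.taxonomy}

    @property
    def bgc_index(self) -> dict[str, BGCRecord]:
        return {b.bgc_id: b for b in self.bgcs}


def lineage_map(taxonomy: Sequence[TaxonomyRecord]) -> dict[str, tuple[str, ...]]:
    """genome_id -> full 7-rank lineage."""
    return {t.genome_id: t.lineage for t in taxonomy}
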