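"""Synthetic corpus generator with exported ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a balanced 7-rank fungal taxonomy; GCF *archetypes*, each a sparse
domain-weight profile with a home taxon at some rank (which controls how
widely the family is distributed); noisy per-BGC domain vectors; a fraction
of singleton archetypes realised as exactly one BGC kingdom-wide; and an
anchored subset of archetypes linked to compounds grouped into structural
NP families.

NP families are formed by letting several archetypes share a common profile
"backbone": members of one family are near each other in feature space
(distance set by their archetype-specific domains) while families are far
apart, which is what makes threshold calibration against NP labels
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    BGC_TYPES,
    RANKS,
    AnchorRecord,
    BGCRecord,
    Dataset,
    TaxonomyRecord,
    ValidationError,
)

#: Probability that an archetype is homed at each rank (how taxonomically
#: restricted the family is).  Most families are species- or genus-specific,
#: mirroring what kingdom-wide surveys observe.
DEFAULT_RANK_PROBS: dict[str, float] = {
    "species": 0.40,
    "genus": 0.20,
    "family": 0.08,
    "order": 0.07,
    "class": 0.07,
    "phylum": 0.10,
    "multi-phyla": 0.08,
}

#: BGC type frequencies, dominated by type I PKS as in fungi.
DEFAULT_TYPE_PROBS: dict[str, float] = {
    "T1PKS": 0.34,
    "NRPS-like": 0.14,
    "NRPS": 0.12,
    "terpene": 0.12,
    "T1PKS&NRPS": 0.10,
    "T1PKS&NRPS-like": 0.09,
    "other": 0.09,
}

MULTI_PHYLA = "multi-phyla"
ROOT_TAXON = "<root>"


@dataclass
class ArchetypeSpec:
    """Ground-truth gene cluster family: a profile plus a taxonomic home."""

    archetype_id: str
    profile: np.ndarray
    home_rank: str
    home_taxon: tuple[str, ...]  # lineage prefix identifying the taxon; () = root
    bgc_type: str
    np_family_id: Optional[str]
    occupancy_prob: float
    singleton: bool = False
    domain_order: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (self.profile > 0).any():
            raise ValidationError(f"{self.archetype_id}: profile has no positive entry")
        if not 0 < self.occupancy_prob <= 1:
            raise ValidationError(f"{self.archetype_id}: occupancy_prob out of (0,1]")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus.

    Defaults describe the study conditions: BGC lengths 0.8-242 kb, roughly
    half of the families singletons, sparse archetype profiles over the
    domain vocabulary with small additive noise, and ~30% of realised
    families anchored to a known compound.
    """

    seed: int = 42
    n_phyla: int = 2
    fanout: dict = field(
        default_factory=lambda: {
            "class": 2,
            "order": 2,
            "family": 2,
            "genus": 2,
            "species": 2,
        }
    )
    n_genomes: int = 300
    vocab_size: int = 150
    n_archetypes: int = 150
    singleton_fraction: float = 0.5
    noise_sd: float = 3.0
    anchor_fraction: float = 0.3
    occupancy_prob: float = 0.6
    length_range_kb: tuple[float, float] = (0.8, 242.0)
    rank_probs: dict = field(default_factory=lambda: dict(DEFAULT_RANK_PROBS))
    type_probs: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_PROBS))

    def validate(self) -> None:
        if self.n_phyla < 1 or self.n_genomes < 1 or self.vocab_size < 1:
            raise ValidationError("counts must be >= 1")
        if self.n_archetypes < 1:
            raise ValidationError("n_archetypes must be >= 1")
        for rank in ("class", "order", "family", "genus", "species"):
            if self.fanout.get(rank, 0) < 1:
                raise ValidationError(f"fanout[{rank}] must be >= 1 (zero leaves)")
        for frac in (self.singleton_fraction, self.anchor_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0,1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 < self.occupancy_prob <= 1:
            raise ValidationError("occupancy_prob must lie in (0,1]")
        lo, hi = self.length_range_kb
        if not 0 < lo <= hi:
            raise ValidationError("length_range_kb must be positive and ordered")


@dataclass
class GroundTruth:
    """Everything recovery tests need: the true partition and richness."""

    bgc_to_archetype: dict[str, str]
    archetype_to_np: dict[str, Optional[str]]
    per_genus_richness: dict[tuple[str, ...], int]
    archetypes: list[ArchetypeSpec]

    def min_interarchetype_distance(self) -> float:
        """Smallest Euclidean distance between distinct L2-normalised
        archetype profiles (restricted to archetypes that generated BGCs
        is the caller's concern; this uses all archetypes)."""
        profiles = np.stack([a.profile for a in self.archetypes])
        norms = np.linalg.norm(profiles, axis=1, keepdims=True)
        unit = profiles / norms
        gram = unit @ unit.T
        d2 = np.maximum(2.0 - 2.0 * gram, 0.0)
        np.fill_diagonal(d2, np.inf)
        return float(np.sqrt(d2.min()))


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def generate_taxonomy(config: GeneratorConfig) -> list[TaxonomyRecord]:
    """Balanced taxonomy tree with the configured fan-outs; genomes are
    assigned to species uniformly at random (balanced in expectation)."""
    config.validate()
    rng = _rng(config.seed, 0)
    species: list[tuple[str, ...]] = []

    def expand(prefix: tuple[str, ...], depth: int) -> None:
        # depth indexes RANKS; prefix covers RANKS[:depth]
        if depth == 6:  # species level reached; organism added per genome
            species.append(prefix)
            return
        rank = RANKS[depth]
        n = config.n_phyla if rank == "phylum" else config.fanout[rank]
        for i in range(n):
            name = f"{prefix[-1]}_{rank[0]}{i + 1}" if prefix else f"phy{i + 1}"
            expand(prefix + (name,), depth + 1)

    expand((), 0)
    if not species:
        raise ValidationError("taxonomy fan-out produced zero species")
    picks = rng.integers(0, len(species), size=config.n_genomes)
    strain_counter: dict[tuple[str, ...], int] = {}
    records = []
    for i, s in enumerate(picks):
        lineage6 = species[s]
        k = strain_counter.get(lineage6, 0) + 1
        strain_counter[lineage6] = k
        organism = f"{lineage6[-1]}_str{k}"
        records.append(
            TaxonomyRecord(genome_id=f"G{i:05d}", lineage=lineage6 + (organism,))
        )
    return records


def _draw_support(rng: np.random.Generator, vocab_size: int, k: int) -> np.ndarray:
    return rng.choice(vocab_size, size=min(k, vocab_size), replace=False)


def _make_archetypes(
    config: GeneratorConfig,
    taxonomy: list[TaxonomyRecord],
    rng: np.random.Generator,
) -> list[ArchetypeSpec]:
    v = config.vocab_size
    backbone_size = max(2, round(0.08 * v))
    specific_size = max(1, round(0.03 * v))

    # taxa with at least one genome, per rank, as lineage prefixes
    taxa_by_rank: dict[str, list[tuple[str, ...]]] = {}
    for rank_i, rank in enumerate(RANKS[:6]):
        taxa = sorted({t.lineage[: rank_i + 1] for t in taxonomy})
        taxa_by_rank[rank] = taxa

    singleton = rng.random(config.n_archetypes) < config.singleton_fraction
    n_regular = int((~singleton).sum())
    n_backbones = max(1, round(n_regular / 3))

    def new_backbone() -> np.ndarray:
        b = np.zeros(v)
        b[_draw_support(rng, v, backbone_size)] = rng.uniform(50, 100, size=backbone_size)
        return b

    backbones = [new_backbone() for _ in range(n_backbones)]
    backbone_of_regular = rng.integers(0, n_backbones, size=config.n_archetypes)

    ranks = list(DEFAULT_RANK_PROBS)
    rank_p = np.array([config.rank_probs[r] for r in ranks], dtype=float)
    rank_p /= rank_p.sum()
    types = sorted(config.type_probs)
    type_p = np.array([config.type_probs[t] for t in types], dtype=float)
    type_p /= type_p.sum()

    archetypes: list[ArchetypeSpec] = []
    n_np = 0
    for i in range(config.n_archetypes):
        if singleton[i]:
            backbone = new_backbone()
            np_family = f"NPC_S{i:04d}"
        else:
            bi = int(backbone_of_regular[i])
            backbone = backbones[bi]
            np_family = f"NPC{bi:04d}"
        n_np += 1
        profile = backbone.copy()
        extra = _draw_support(rng, v, specific_size)
        profile[extra] += rng.uniform(20, 40, size=len(extra))
        home_rank = ranks[rng.choice(len(ranks), p=rank_p)]
        if home_rank == MULTI_PHYLA:
            home_taxon: tuple[str, ...] = ()
        else:
            taxa = taxa_by_rank[home_rank]
            home_taxon = taxa[rng.integers(0, len(taxa))]
        support = np.flatnonzero(profile > 0)
        order = tuple(support[rng.permutation(len(support))].tolist())
        archetypes.append(
            ArchetypeSpec(
                archetype_id=f"A{i:04d}",
                profile=profile,
                home_rank=home_rank,
                home_taxon=home_taxon,
                bgc_type=types[rng.choice(len(types), p=type_p)],
                np_family_id=np_family,
                occupancy_prob=config.occupancy_prob,
                singleton=bool(singleton[i]),
                domain_order=order,
            )
        )
    return archetypes


def _compatible_genomes(
    arch: ArchetypeSpec, taxonomy: list[TaxonomyRecord]
) -> list[TaxonomyRecord]:
    if not arch.home_taxon:
        return list(taxonomy)
    k = len(arch.home_taxon)
    return [t for t in taxonomy if t.lineage[:k] == arch.home_taxon]


def generate_dataset(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Draw a full synthetic corpus plus its ground truth.

    Each genome carries, for every non-singleton archetype whose home taxon
    lies on its lineage, one BGC with probability ``occupancy_prob``; each
    singleton archetype is realised as one BGC in one random compatible
    genome.  BGC vectors are the archetype profile plus isotropic Gaussian
    noise truncated at zero.
    """
    config.validate()
    taxonomy = generate_taxonomy(config)
    arch_rng = _rng(config.seed, 1)
    bgc_rng = _rng(config.seed, 2)
    anchor_rng = _rng(config.seed, 3)

    vocabulary = tuple(f"D{i:04d}" for i in range(config.vocab_size))
    archetypes = _make_archetypes(config, taxonomy, arch_rng)

    # (genome, archetype) incidence draws, in deterministic order
    placements: list[tuple[str, ArchetypeSpec]] = []
    for arch in archetypes:
        hosts = _compatible_genomes(arch, taxonomy)
        if not hosts:
            continue
        if arch.singleton:
            g = hosts[bgc_rng.integers(0, len(hosts))]
            placements.append((g.genome_id, arch))
        else:
            carried = bgc_rng.random(len(hosts)) < arch.occupancy_prob
            for g, c in zip(hosts, carried):
                if c:
                    placements.append((g.genome_id, arch))
    placements.sort(key=lambda p: (p[0], p[1].archetype_id))

    lo, hi = config.length_range_kb
    bgcs: list[BGCRecord] = []
    bgc_to_archetype: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for i, (genome_id, arch) in enumerate(placements):
        vec = None
        for _ in range(10):
            cand = arch.profile + bgc_rng.normal(0.0, config.noise_sd, size=config.vocab_size)
            cand = np.maximum(cand, 0.0)
            if (cand > 0).any():
                vec = cand
                break
        if vec is None:
            raise ValidationError(
                f"noise produced an all-zero vector for archetype {arch.archetype_id}"
            )
        bgc_id = f"B{i:06d}"
        domains = {vocabulary[j]: float(vec[j]) for j in np.flatnonzero(vec > 0)}
        order = tuple(vocabulary[j] for j in arch.domain_order if vec[j] > 0)
        bgcs.append(
            BGCRecord(
                bgc_id=bgc_id,
                genome_id=genome_id,
                bgc_type=arch.bgc_type,
                length_kb=float(bgc_rng.uniform(lo, hi)),
                domains=domains,
                domain_order=order or None,
            )
        )
        bgc_to_archetype[bgc_id] = arch.archetype_id
        members.setdefault(arch.archetype_id, []).append(bgc_id)

    # anchors: a fraction of realised archetypes, one member BGC each
    realised = [a for a in archetypes if a.archetype_id in members]
    n_anchored = round(config.anchor_fraction * len(realised))
    anchors: list[AnchorRecord] = []
    if n_anchored > 0:
        idx = anchor_rng.choice(len(realised), size=n_anchored, replace=False)
        for j, ai in enumerate(sorted(idx.tolist())):
            arch = realised[ai]
            mem = members[arch.archetype_id]
            bgc_id = mem[anchor_rng.integers(0, len(mem))]
            anchors.append(
                AnchorRecord(
                    bgc_id=bgc_id,
                    compound_id=f"CPD{j:05d}",
                    np_cluster_id=arch.np_family_id,
                )
            )
        anchors.sort(key=lambda a: a.bgc_id)

    per_genus = _per_genus_richness(archetypes, taxonomy, bgc_to_archetype, bgcs)
    dataset = Dataset(
        taxonomy=taxonomy,
        bgcs=bgcs,
        anchors=anchors,
        domain_vocabulary=vocabulary,
    )
    truth = GroundTruth(
        bgc_to_archetype=bgc_to_archetype,
        archetype_to_np={a.archetype_id: a.np_family_id for a in archetypes},
        per_genus_richness=per_genus,
        archetypes=archetypes,
    )
    return dataset, truth


def _per_genus_richness(
    archetypes: list[ArchetypeSpec],
    taxonomy: list[TaxonomyRecord],
    bgc_to_archetype: dict[str, str],
    bgcs: list[BGCRecord],
) -> dict[tuple[str, ...], int]:
    """True archetype richness per genus (lineage prefix through genus):
    non-singleton archetypes whose home taxon contains, or is contained in,
    the genus, plus singleton archetypes realised inside the genus."""
    genus_of_genome = {t.genome_id: t.lineage[:5] for t in taxonomy}
    genera = sorted(set(genus_of_genome.values()))
    richness = {g: set() for g in genera}
    for arch in archetypes:
        if arch.singleton:
            continue
        k = len(arch.home_taxon)
        for g in genera:
            if k <= 5:
                compatible = g[:k] == arch.home_taxon
            else:
                compatible = arch.home_taxon[:5] == g
            if compatible:
                richness[g].add(arch.archetype_id)
    genome_genus = genus_of_genome
    arch_by_id = {a.archetype_id: a for a in archetypes}
    for b in bgcs:
        arch = arch_by_id[bgc_to_archetype[b.bgc_id]]
        if arch.singleton:
            richness[genome_genus[b.genome_id]].add(arch.archetype_id)
    return {g: len(s) for g, s in richness.items()}


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Export the BGC -> archetype -> NP-family map as a TSV."""
    import pandas as pd

    rows = [
        (bgc, arch, truth.archetype_to_np.get(arch) or "")
        for bgc, arch in sorted(truth.bgc_to_archetype.items())
    ]
    pd.DataFrame(rows, columns=["bgc_id", "archetype_id", "np_family_id"]).to_csv(
        path, sep="\t", index=False
    )
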