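"""Threshold-governed clustering of BGCs into gene cluster families.

BGCs are embedded as L2-normalised domain-weight vectors, so Euclidean
distances lie in [0, sqrt(2)].  Families are formed by incremental
nearest-centroid clustering under a distance threshold ``t_clust`` (the
quantity calibrated against known natural-product clusters), followed by a
refinement pass that freezes the centroids and reassigns every BGC to its
nearest one.  The scheme is deterministic: BGCs are visited in ascending
``bgc_id`` order and ties break toward the lowest family id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import BGCRecord, Dataset, ValidationError

#: Default clustering threshold in normalised-distance units.
DEFAULT_T_CLUST = 0.55

SIZE_BINS = ("1", "2-10", "11-100", ">100")


@dataclass
class FeatureVector:
    """A BGC as a unit vector over the domain vocabulary."""

    bgc_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.values))
        if abs(norm - 1.0) > 1e-9:
            raise ValidationError(f"{self.bgc_id}: feature vector not L2-normalised")


def featurize(bgc: BGCRecord, vocabulary: Sequence[str]) -> FeatureVector:
    """Lay the sparse domain weights over ``vocabulary`` and L2-normalise."""
    index = {name: i for i, name in enumerate(vocabulary)}
    vec = np.zeros(len(vocabulary))
    for name, w in bgc.domains.items():
        if name not in index:
            raise ValidationError(f"{bgc.bgc_id}: domain {name!r} not in vocabulary")
        vec[index[name]] += w
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValidationError(f"{bgc.bgc_id}: all-zero feature vector")
    return FeatureVector(bgc_id=bgc.bgc_id, values=vec / norm)


def featurize_all(dataset: Dataset) -> list[FeatureVector]:
    index = {name: i for i, name in enumerate(dataset.domain_vocabulary)}
    out = []
    for bgc in dataset.bgcs:
        vec = np.zeros(len(index))
        for name, w in bgc.domains.items():
            vec[index[name]] += w
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValidationError(f"{bgc.bgc_id}: all-zero feature vector")
        out.append(FeatureVector(bgc_id=bgc.bgc_id, values=vec / norm))
    return out


@dataclass
class GCFAssignment:
    """A partition of BGCs into families at a given threshold."""

    threshold: float
    membership: dict[str, int]
    centroids: dict[int, np.ndarray]

    @property
    def n_gcfs(self) -> int:
        return len(self.centroids)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {g: [] for g in self.centroids}
        for bgc_id in sorted(self.membership):
            out[self.membership[bgc_id]].append(bgc_id)
        return out

    def sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {g: 0 for g in self.centroids}
        for g in self.membership.values():
            sizes[g] += 1
        return sizes


def cluster(vectors: Iterable[FeatureVector], t_clust: float) -> GCFAssignment:
    """Two-pass nearest-centroid clustering at distance threshold ``t_clust``.

    Pass 1 visits BGCs in ascending ``bgc_id`` order, assigning each to the
    nearest existing centroid if within ``t_clust`` (centroids are running
    means) and opening a new family otherwise.  Pass 2 freezes the pass-1
    centroids and reassigns every BGC to its nearest centroid; families left
    empty are dropped and ids re-densified in creation order.
    """
    vecs = sorted(vectors, key=lambda v: v.bgc_id)
    if not vecs:
        raise ValidationError("no feature vectors to cluster")
    if t_clust < 0:
        raise ValidationError("t_clust must be >= 0")
    dim = len(vecs[0].values)
    X = np.stack([v.values for v in vecs])

    # pass 1: incremental assignment with running-mean centroids
    cap = 16
    sums = np.zeros((cap, dim))
    counts = np.zeros(cap, dtype=np.int64)
    k = 0
    assign1 = np.empty(len(vecs), dtype=np.int64)
    for i in range(len(vecs)):
        x = X[i]
        if k > 0:
            means = sums[:k] / counts[:k, None]
            d = np.linalg.norm(means - x, axis=1)
            j = int(np.argmin(d))
            if d[j] <= t_clust:
                assign1[i] = j
                sums[j] += x
                counts[j] += 1
                continue
        if k == cap:
            cap *= 2
            sums = np.vstack([sums, np.zeros((cap - k, dim))])
            counts = np.concatenate([counts, np.zeros(cap - k, dtype=np.int64)])
        sums[k] = x
        counts[k] = 1
        assign1[i] = k
        k += 1

    centroids = sums[:k] / counts[:k, None]

    # pass 2: frozen centroids, global nearest reassignment (ties -> lowest id)
    d2 = (
        (X**2).sum(axis=1)[:, None]
        - 2.0 * X @ centroids.T
        + (centroids**2).sum(axis=1)[None, :]
    )
    assign2 = np.argmin(d2, axis=1)

    # drop emptied families, re-densify ids in creation order
    used = np.unique(assign2)
    remap = {int(old): new for new, old in enumerate(used.tolist())}
    membership = {v.bgc_id: remap[int(a)] for v, a in zip(vecs, assign2)}
    centroid_map = {remap[int(old)]: centroids[int(old)].copy() for old in used}
    return GCFAssignment(threshold=t_clust, membership=membership, centroids=centroid_map)


@dataclass
class SizeDistribution:
    """GCF/BGC tallies in the size bins =1, 2-10, 11-100, >100."""

    gcf_counts: dict[str, int]
    bgc_counts: dict[str, int]
    singleton_gcf_fraction: float
    singleton_bgc_fraction: float


def size_distribution(assignment: GCFAssignment) -> SizeDistribution:
    sizes = list(assignment.sizes().values())
    if not sizes:
        raise ValidationError("empty assignment")

    def bin_of(s: int) -> str:
        if s == 1:
            return "1"
        if s <= 10:
            return "2-10"
        if s <= 100:
            return "11-100"
        return ">100"

    gcf_counts = {b: 0 for b in SIZE_BINS}
    bgc_counts = {b: 0 for b in SIZE_BINS}
    for s in sizes:
        b = bin_of(s)
        gcf_counts[b] += 1
        bgc_counts[b] += s
    total_gcfs = len(sizes)
    total_bgcs = sum(sizes)
    return SizeDistribution(
        gcf_counts=gcf_counts,
        bgc_counts=bgc_counts,
        singleton_gcf_fraction=gcf_counts["1"] / total_gcfs,
        singleton_bgc_fraction=bgc_counts["1"] / total_bgcs,
    )
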