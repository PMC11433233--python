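"""Readers and writers for the tab-separated exchange formats.

Three tables travel between stages: ``taxonomy.tsv`` (genome_id plus the
seven rank columns), ``bgcs.tsv`` (one row per BGC with a sparse domain
vector encoded ``name:weight;name:weight``) and ``anchors.tsv``
(bgc_id, compound_id, np_cluster_id).  A thin importer turns standard
``hmmscan --domtblout`` output into a single BGC's domain vector.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .model import (
    RANKS,
    AnchorRecord,
    BGCRecord,
    Dataset,
    FormatError,
    TaxonomyRecord,
    ValidationError,
)

TAXONOMY_COLUMNS = ("genome_id",) + RANKS
BGC_COLUMNS = ("bgc_id", "genome_id", "bgc_type", "length_kb", "domains", "domain_order")
ANCHOR_COLUMNS = ("bgc_id", "compound_id", "np_cluster_id")


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def fill_lineage(raw: Sequence[str]) -> tuple[str, ...]:
    """Complete a partially specified lineage.

    Each empty rank below phylum is replaced with ``unclassified_<parent>``
    where the parent is the (already filled) next-higher rank.  The rule is
    deterministic and idempotent.  An empty phylum is rejected: genomes must
    be placed at least at the phylum level.
    """
    vals = [str(v).strip() for v in raw]
    if len(vals) != len(RANKS):
        raise ValidationError(f"lineage must have {len(RANKS)} entries")
    if not vals[0]:
        raise ValidationError("empty phylum: genomes must be classified at phylum level")
    filled = [vals[0]]
    for v in vals[1:]:
        filled.append(v if v else f"unclassified_{filled[-1]}")
    return tuple(filled)


def read_taxonomy(path) -> list[TaxonomyRecord]:
    df = _read_tsv(path, TAXONOMY_COLUMNS)
    records: list[TaxonomyRecord] = []
    seen: set[str] = set()
    # positional access: "class" is a keyword and breaks itertuples attributes
    cols = [df[c].tolist() for c in TAXONOMY_COLUMNS]
    for i in range(len(df)):
        gid = str(cols[0][i])
        if gid in seen:
            raise ValidationError(f"duplicate genome_id {gid}")
        seen.add(gid)
        lineage = fill_lineage([cols[j + 1][i] for j in range(len(RANKS))])
        records.append(TaxonomyRecord(genome_id=gid, lineage=lineage))
    return records


def parse_sparse_vector(text: str) -> dict[str, float]:
    """Parse the ``name:weight;name:weight`` sparse-vector dialect."""
    text = text.strip()
    if not text:
        raise ValidationError("empty domain vector field")
    domains: dict[str, float] = {}
    for pair in text.split(";"):
        name, sep, weight = pair.rpartition(":")
        if not sep or not name:
            raise FormatError(f"malformed sparse entry {pair!r}")
        w = float(weight)
        if w < 0:
            raise ValidationError(f"negative weight for domain {name}")
        domains[name] = domains.get(name, 0.0) + w
    return domains


def format_sparse_vector(domains: dict[str, float]) -> str:
    return ";".join(f"{k}:{domains[k]!r}" for k in sorted(domains))


def read_bgc_table(
    path, vocabulary: Optional[Sequence[str]] = None
) -> tuple[list[BGCRecord], tuple[str, ...]]:
    """Read BGC records; returns ``(records, vocabulary)``.

    If no vocabulary is supplied it is inferred as the sorted union of all
    domain names seen in the table.
    """
    df = _read_tsv(path, BGC_COLUMNS[:5])
    has_order = "domain_order" in df.columns
    records: list[BGCRecord] = []
    for row in df.itertuples(index=False):
        domains = parse_sparse_vector(row.domains)
        order = None
        if has_order and str(row.domain_order).strip():
            order = tuple(str(row.domain_order).split(","))
        records.append(
            BGCRecord(
                bgc_id=str(row.bgc_id),
                genome_id=str(row.genome_id),
                bgc_type=str(row.bgc_type),
                length_kb=float(row.length_kb),
                domains=domains,
                domain_order=order,
            )
        )
    if vocabulary is None:
        names: set[str] = set()
        for rec in records:
            names.update(rec.domains)
        vocabulary = tuple(sorted(names))
    return records, tuple(vocabulary)


def read_anchor_table(path) -> list[AnchorRecord]:
    df = _read_tsv(path, ANCHOR_COLUMNS)
    records = [
        AnchorRecord(str(r.bgc_id), str(r.compound_id), str(r.np_cluster_id))
        for r in df.itertuples(index=False)
    ]
    seen: set[str] = set()
    for a in records:
        if a.bgc_id in seen:
            raise ValidationError(f"duplicate anchor for {a.bgc_id}")
        seen.add(a.bgc_id)
    return records


# --- hmmscan domtblout import -------------------------------------------------

# 0-based column offsets in the standard --domtblout layout
_DOM_TARGET = 0
_DOM_QUERY = 3
_DOM_IEVALUE = 12
_DOM_SCORE = 13
_DOM_ALI_FROM = 17


def import_domtblout(
    path,
    genome_id: str,
    bgc_id: str,
    evalue_cutoff: float = 1e-5,
    bgc_type: str = "other",
    length_kb: float = 1.0,
) -> BGCRecord:
    """Build a BGC domain vector from hmmscan domain-table output.

    Hits whose independent E-value exceeds ``evalue_cutoff`` are discarded;
    the weight of a domain is the sum of the domain bitscores of its retained
    hits, and ``domain_order`` lists retained hits ordered by query appearance
    and alignment start.
    """
    hits: list[tuple[int, int, str, float]] = []
    query_order: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 22:
                raise FormatError(f"{path}: short domtblout line: {line.rstrip()!r}")
            ievalue = float(parts[_DOM_IEVALUE])
            if ievalue > evalue_cutoff:
                continue
            query = parts[_DOM_QUERY]
            if query not in query_order:
                query_order[query] = len(query_order)
            hits.append(
                (
                    query_order[query],
                    int(parts[_DOM_ALI_FROM]),
                    parts[_DOM_TARGET],
                    float(parts[_DOM_SCORE]),
                )
            )
    if not hits:
        raise ValidationError(f"{path}: no hits passing i-E-value <= {evalue_cutoff}")
    hits.sort(key=lambda h: (h[0], h[1]))
    domains: dict[str, float] = {}
    order: list[str] = []
    for _, _, name, score in hits:
        domains[name] = domains.get(name, 0.0) + score
        order.append(name)
    return BGCRecord(
        bgc_id=bgc_id,
        genome_id=genome_id,
        bgc_type=bgc_type,
        length_kb=length_kb,
        domains=domains,
        domain_order=tuple(order),
    )


# --- dataset round-trip -------------------------------------------------------

def write_tables(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write taxonomy.tsv, bgcs.tsv, anchors.tsv and vocabulary.txt.

    Round-trip safe: ``read_dataset(out_dir)`` reproduces the dataset exactly
    (float weights are serialised with ``repr`` so they survive the trip).
    """
    out = Path(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "taxonomy": out / "taxonomy.tsv",
        "bgcs": out / "bgcs.tsv",
        "anchors": out / "anchors.tsv",
    }
    tax = pd.DataFrame(
        [(t.genome_id, *t.lineage) for t in dataset.taxonomy],
        columns=list(TAXONOMY_COLUMNS),
    )
    tax.to_csv(paths["taxonomy"], sep="\t", index=False)
    bgc = pd.DataFrame(
        [
            (
                b.bgc_id,
                b.genome_id,
                b.bgc_type,
                repr(b.length_kb),
                format_sparse_vector(b.domains),
                ",".join(b.domain_order) if b.domain_order else "",
            )
            for b in dataset.bgcs
        ],
        columns=list(BGC_COLUMNS),
    )
    bgc.to_csv(paths["bgcs"], sep="\t", index=False)
    anch = pd.DataFrame(
        [(a.bgc_id, a.compound_id, a.np_cluster_id) for a in dataset.anchors],
        columns=list(ANCHOR_COLUMNS),
    )
    anch.to_csv(paths["anchors"], sep="\t", index=False)
    vocab = out / "vocabulary.txt"
    vocab.write_text("\n".join(dataset.domain_vocabulary) + "\n")
    paths["vocabulary"] = vocab
    return paths


def read_dataset(in_dir) -> Dataset:
    d = Path(in_dir)
    vocab_file = d / "vocabulary.txt"
    vocabulary: Optional[tuple[str, ...]] = None
    if vocab_file.exists():
        vocabulary = tuple(vocab_file.read_text().split())
    taxonomy = read_taxonomy(d / "taxonomy.tsv")
    bgcs, vocabulary = read_bgc_table(d / "bgcs.tsv", vocabulary)
    anchors_path = d / "anchors.tsv"
    anchors = read_anchor_table(anchors_path) if anchors_path.exists() else []
    return Dataset(
        taxonomy=taxonomy,
        bgcs=bgcs,
        anchors=anchors,
        domain_vocabulary=vocabulary,
    )
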