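"""End-to-end pipeline: generate/ingest -> calibrate -> cluster ->
diversity -> rarefaction -> annotation -> report.

Every stage writes a tab-separated table into the output directory; a run
with a fixed seed is byte-identical across invocations.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import annotation, calibration, clustering, diversity, rarefaction
from .report import report as make_report
from .io import read_dataset, write_tables
from .model import Dataset, ValidationError
from .simulate import GeneratorConfig, GroundTruth, generate_dataset, write_ground_truth

log = logging.getLogger("fungcf")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``threshold`` / ``grid`` must be set: either the clustering
    threshold is given, or it is calibrated on the anchored BGCs over the
    grid (a "start:stop:step" string).
    """

    out_dir: str = "fungcf_out"
    seed: int = 42
    input_dir: Optional[str] = None  # None -> synthetic generation
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    threshold: Optional[float] = None
    grid: Optional[str] = "0.1:1.1:0.05"
    endpoint: int = rarefaction.DEFAULT_ENDPOINT
    n_knots: int = rarefaction.DEFAULT_KNOTS
    query_file: Optional[str] = None
    min_gene_frac: float = 0.6
    gene_jaccard: float = 0.5
    network_cutoff: float = 0.5
    n_focal_genera: int = 10
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.threshold is None) == (self.grid is None):
            raise ValidationError(
                "exactly one of threshold / grid must be configured"
            )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_keys = {f.name for f in dataclasses.fields(GeneratorConfig)}
        run_keys = {f.name for f in dataclasses.fields(cls)} - {"generator"}
        gen_kwargs = {k: v for k, v in raw.items() if k in gen_keys}
        run_kwargs = {k: v for k, v in raw.items() if k in run_keys}
        unknown = set(raw) - gen_keys - run_keys
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**run_kwargs, generator=GeneratorConfig(**gen_kwargs))
        if "seed" in raw:
            cfg.generator.seed = int(raw["seed"])
        return cfg


def parse_grid(spec: str) -> list[float]:
    try:
        start, stop, step = (float(x) for x in spec.split(":"))
    except ValueError as exc:
        raise ValidationError(f"grid must be 'start:stop:step', got {spec!r}") from exc
    return calibration.default_grid(start, stop, step)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    os.makedirs(out, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        return _run_stages(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path) -> Path:
    truth: Optional[GroundTruth] = None
    if config.input_dir is not None:
        log.info("ingest: reading dataset from %s", config.input_dir)
        dataset = read_dataset(config.input_dir)
    else:
        config.generator.seed = config.seed
        log.info("generate: synthetic dataset, seed=%d", config.seed)
        dataset, truth = generate_dataset(config.generator)
        write_tables(dataset, out)
        write_ground_truth(truth, out / "ground_truth.tsv")
    log.info(
        "dataset: %d genomes, %d BGCs, %d anchors",
        len(dataset.taxonomy),
        len(dataset.bgcs),
        len(dataset.anchors),
    )

    # threshold: explicit or calibrated on the anchored subset
    if config.threshold is not None:
        t_clust = config.threshold
        log.info("threshold: fixed at %.3f", t_clust)
    else:
        cal = calibration.calibrate(dataset, parse_grid(config.grid))
        _write(cal.to_frame(), out / "calibration.tsv")
        t_clust = cal.chosen_t
        log.info("calibrate: chose T=%.3f", t_clust)

    vectors = clustering.featurize_all(dataset)
    assignment = clustering.cluster(vectors, t_clust)
    log.info("cluster: %d GCFs at T=%.3f", assignment.n_gcfs, t_clust)
    rows = []
    cents = assignment.centroids
    vec_by_id = {v.bgc_id: v for v in vectors}
    for bgc_id in sorted(assignment.membership):
        gcf = assignment.membership[bgc_id]
        dist = float(
            ((vec_by_id[bgc_id].values - cents[gcf]) ** 2).sum() ** 0.5
        )
        rows.append((bgc_id, gcf, repr(dist)))
    _write(
        pd.DataFrame(rows, columns=["bgc_id", "gcf_id", "distance_to_centroid"]),
        out / "gcf_assignments.tsv",
    )
    sizes = clustering.size_distribution(assignment)
    _write(
        pd.DataFrame(
            [
                (b, sizes.gcf_counts[b], sizes.bgc_counts[b])
                for b in clustering.SIZE_BINS
            ],
            columns=["size_bin", "n_gcfs", "n_bgcs"],
        ),
        out / "gcf_sizes.tsv",
    )

    matrix = diversity.incidence(assignment, dataset)
    profile = diversity.specificity(matrix, dataset.taxonomy)
    _write(
        pd.DataFrame(
            sorted(profile.gcf_class.items()), columns=["gcf_id", "specificity"]
        ),
        out / "specificity.tsv",
    )
    types = diversity.gcf_types(assignment, dataset)
    counts, pct = diversity.type_by_range_matrix(profile, types)
    counts.index.name = "specificity"
    counts.reset_index().to_csv(out / "type_by_range.tsv", sep="\t", index=False)
    _write(
        diversity.phylum_summary(
            matrix, dataset.taxonomy, dataset.anchors, assignment, dataset
        ),
        out / "phylum_summary.tsv",
    )
    _write(diversity.rank_variance(matrix, dataset.taxonomy).to_frame(), out / "rank_variance.tsv")

    # per-genus rarefaction to pGCF
    genus_of = {t.genome_id: t.taxon("genus") for t in dataset.taxonomy}
    genera: dict[str, list[str]] = {}
    for g, genus in genus_of.items():
        genera.setdefault(genus, []).append(g)
    np_by_genus: dict[str, set[str]] = {}
    genome_of = {b.bgc_id: b.genome_id for b in dataset.bgcs}
    for a in dataset.anchors:
        np_by_genus.setdefault(genus_of[genome_of[a.bgc_id]], set()).add(a.compound_id)
    curve_rows = []
    pgcf_rows = []
    pgcf_by_genus = {}
    for genus in sorted(genera):
        c = rarefaction.curve(
            matrix, genera[genus], endpoint=config.endpoint, n_knots=config.n_knots, label=genus
        )
        pgcf_by_genus[genus] = c.pgcf
        curve_rows.extend((genus, t, repr(est)) for t, est in c.knots)
        pgcf_rows.append(
            (genus, len(genera[genus]), c.s_obs, repr(c.chao2), repr(c.pgcf),
             len(np_by_genus.get(genus, ())))
        )
    np_counts = {g: len(s) for g, s in np_by_genus.items()}
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        flagged = set(rarefaction.promising_genera(pgcf_by_genus, np_counts))
    _write(
        pd.DataFrame(curve_rows, columns=["group", "t", "estimate"]),
        out / "rarefaction_curves.tsv",
    )
    _write(
        pd.DataFrame(
            [r + (r[0] in flagged,) for r in pgcf_rows],
            columns=["genus", "n_genomes", "s_obs", "chao2", "pgcf", "np_count", "promising"],
        ),
        out / "pgcf.tsv",
    )

    # annotation
    linkage = annotation.link_anchors(assignment, dataset.anchors)
    _write(
        pd.DataFrame(
            linkage.annotated,
            columns=["bgc_id", "gcf_id", "np_cluster_ids", "ambiguous"],
        ),
        out / "annotations.tsv",
    )
    log.info(
        "annotate: %d known GCFs covering %d BGCs",
        linkage.n_known_gcfs,
        linkage.n_annotated_bgcs,
    )

    # optional drug-similarity search + network
    hits_per_query: dict[str, list[str]] = {}
    if config.query_file:
        queries = annotation.read_query_file(config.query_file)
        reps = annotation.representatives(assignment, config.seed)
        bgc_index = dataset.bgc_index
        drug_of: dict[str, str] = {}
        all_hits: list[str] = []
        for q in queries:
            hits = annotation.query_search(
                q,
                reps,
                dataset,
                min_gene_frac=config.min_gene_frac,
                gene_jaccard=config.gene_jaccard,
                assignment=assignment,
            )
            hits_per_query[q.query_id] = hits
            for h in hits:
                drug_of.setdefault(h, q.query_id)
            all_hits.extend(hits)
        all_hits = sorted(set(all_hits))
        if all_hits:
            net = annotation.network(
                [bgc_index[h] for h in all_hits],
                config.network_cutoff,
                taxonomy=dataset.taxonomy,
                drug_of=drug_of,
            )
            edges = sorted(net.graph.edges(data="weight"))
            _write(
                pd.DataFrame(
                    [(u, v, repr(w)) for u, v, w in edges],
                    columns=["source", "target", "weight"],
                ),
                out / "network_edges.tsv",
            )
        top = sorted(pgcf_by_genus, key=lambda g: -pgcf_by_genus[g])[: config.n_focal_genera]
        census = annotation.drug_census(hits_per_query, dataset, top)
        _write(
            pd.DataFrame(
                [
                    (r.query_id, r.total_hits, r.focal_hits, repr(r.focal_pct))
                    for r in census
                ],
                columns=["query_id", "total_hits", "focal_hits", "focal_pct"],
            ),
            out / "drug_census.tsv",
        )

    # summary report from the counts just computed
    total_gcfs = assignment.n_gcfs
    total_bgcs = len(dataset.bgcs)
    top_genus = max(pgcf_by_genus, key=lambda g: (pgcf_by_genus[g], g))
    genus_gcfs = int(matrix.df[genera[top_genus]].any(axis=1).sum())
    counts_in: dict[str, object] = {
        "total_gcfs": total_gcfs,
        "total_bgcs": total_bgcs,
        "known_gcfs": linkage.n_known_gcfs,
        "singleton_gcf_fraction": sizes.singleton_gcf_fraction,
        "genus_gcfs": genus_gcfs,
        "pgcf": pgcf_by_genus[top_genus],
        "gcfs": genus_gcfs,
    }
    if hits_per_query:
        all_hits_flat = [h for hs in hits_per_query.values() for h in hs]
        top = sorted(pgcf_by_genus, key=lambda g: -pgcf_by_genus[g])[: config.n_focal_genera]
        census = annotation.drug_census(hits_per_query, dataset, top)
        counts_in["total_hits"] = len(all_hits_flat)
        counts_in["focal_hits"] = sum(r.focal_hits for r in census)
    summary = make_report(counts_in)
    _write(summary.to_frame(), out / "summary.tsv")
    log.info("report: %d statistics", len(summary.stats))
    return out
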