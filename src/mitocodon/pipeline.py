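"""Batch orchestration: per-genome and cross-genome analyses plus reporting.

A run takes annotated genomes (GenBank flat files or FASTA + feature
table), computes composition/skew tables, per-gene codon-bias scores
(ENC, CAI, positional GC), the taxa x 59 RSCU matrix, the RSCU cluster
tree, per-genome optimal-codon screens, control-region motif scans and
partitions, and gene-order comparisons against the canonical vertebrate
arrangement. Outputs are plain TSV/JSON with fixed schemas; a manifest
records the configuration, package version and input checksums so a run
can be reproduced bit-for-bit.

Per-genome failures are logged and skipped; only an empty result set is
fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .codes import get_code
from .composition import composition_table
from .codon_stats import bias_scores, count_codons
from .clustering import agglomerative_cluster, build_rscu_matrix
from .composition import positional_gc
from .gene_order import (
    OrderSignature, diff_gene_orders, gene_order_signature, spacer_overlap_tally,
)
from .genome_io import (
    MitogenomeRecord, extract_gene_sequence, parse_genbank_record,
    read_fasta_with_features,
)
from .motifs import DEFAULT_MOTIFS, PartitionError, load_motifs_tsv, partition_control_region, scan_motif
from .optimal_codons import screen_optimal_codons
from .synthetic import CANONICAL_ORDER

logger = logging.getLogger("mitocodon")

CANONICAL_SIGNATURE = OrderSignature(
    tuple((name, strand) for name, _cls, strand in CANONICAL_ORDER)
)


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)
    stats_code: str = "standard"  # family layout for RSCU/ENC/CAI
    validation_code: str = "vertebrate_mito"
    delta_threshold: float = 0.08
    group_fraction: float = 0.10
    direction: str = "paper"
    high: str | None = None
    low: str | None = None
    metric: str = "euclidean"
    linkage: str = "average"
    motif_path: str | None = None
    outdir: str = "mitocodon_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_threshold < 0:
            raise ValueError("delta threshold must be >= 0")
        if not 0 < self.group_fraction <= 0.5:
            raise ValueError("group fraction must lie in (0, 0.5]")


@dataclass
class ResultBundle:
    records: list[MitogenomeRecord]
    composition: pd.DataFrame
    gene_bias: pd.DataFrame
    rscu_matrix: pd.DataFrame | None
    cluster: object | None
    optimal_reports: dict[str, object]
    motif_hits: pd.DataFrame
    partitions: dict[str, object]
    order_diffs: dict[str, object]
    adjacency: pd.DataFrame
    manifest: dict


def load_records(inputs: list[str]) -> list[MitogenomeRecord]:
    """Load GenBank files, or FASTA paths paired as ``genome.fa:features.tsv``."""
    records = []
    for item in inputs:
        try:
            if ":" in str(item) and not str(item).endswith((".gb", ".gbk", ".genbank")):
                fasta, table = str(item).split(":", 1)
                records.append(read_fasta_with_features(fasta, table))
            else:
                records.append(parse_genbank_record(item))
        except Exception as exc:
            logger.warning("skipping %s: %s", item, exc)
    return records


def _gene_bias_table(records, stats_code) -> pd.DataFrame:
    rows = []
    for rec in records:
        pcgs = sorted(rec.pcgs, key=lambda f: f.name)
        if not pcgs:
            continue
        seqs = {f.name: extract_gene_sequence(rec, f.name) for f in pcgs}
        tables = {g: count_codons(s, stats_code, source=g) for g, s in seqs.items()}
        reference = None
        for t in tables.values():
            reference = t if reference is None else reference.merged(t, source="PCGs")
        for gene in tables:
            scores = bias_scores(tables[gene], reference, gene=gene)
            pos = positional_gc(seqs[gene])
            rows.append(
                {
                    "taxon": rec.accession, "gene": gene,
                    "ENC": None if scores.enc is None else round(scores.enc, 3),
                    "CAI": None if scores.cai is None else round(scores.cai, 3),
                    "GC_all": round(pos.gc_all, 2), "GC1": round(pos.gc1, 2),
                    "GC2": round(pos.gc2, 2), "GC3": round(pos.gc3, 2),
                }
            )
    return pd.DataFrame(rows)


def analyze_records(records: list[MitogenomeRecord], config: RunConfig) -> ResultBundle:
    """Run every per-genome and cross-genome analysis on loaded records."""
    if not records:
        raise ValueError("no parseable genomes")
    stats_code = get_code(config.stats_code)
    motifs = load_motifs_tsv(config.motif_path) if config.motif_path else DEFAULT_MOTIFS

    composition = composition_table(records)
    gene_bias = _gene_bias_table(records, stats_code)

    rscu_matrix = None
    cluster = None
    if len(records) >= 2:
        rscu_matrix = build_rscu_matrix(records, stats_code)
        if rscu_matrix.shape[0] >= 2:
            cluster = agglomerative_cluster(rscu_matrix, config.metric, config.linkage)
    else:
        logger.info("single genome: clustering skipped")

    optimal_reports = {}
    for rec in records:
        try:
            optimal_reports[rec.accession] = screen_optimal_codons(
                rec, code=stats_code, high=config.high, low=config.low,
                fraction=config.group_fraction, direction=config.direction,
                delta_threshold=config.delta_threshold,
            )
        except Exception as exc:
            logger.warning("%s: optimal-codon screen failed: %s", rec.accession, exc)

    hit_rows = []
    partitions = {}
    for rec in records:
        if not rec.has_feature("CR"):
            continue
        region = extract_gene_sequence(rec, "CR")
        for motif in motifs:
            for hit in scan_motif(region, motif):
                hit_rows.append(
                    {"taxon": rec.accession, "motif": hit.motif, "start": hit.start,
                     "end": hit.end, "mismatches": hit.mismatches,
                     "matched_seq": hit.matched_seq}
                )
        try:
            partitions[rec.accession] = partition_control_region(region, motifs)
        except PartitionError as exc:
            logger.warning("%s: %s", rec.accession, exc)
    motif_hits = pd.DataFrame(
        hit_rows, columns=["taxon", "motif", "start", "end", "mismatches", "matched_seq"]
    )

    order_diffs = {}
    adj_rows = []
    for rec in records:
        try:
            signature = gene_order_signature(rec)
            order_diffs[rec.accession] = diff_gene_orders(CANONICAL_SIGNATURE, signature)
            spacers, overlaps = spacer_overlap_tally(rec)
            for kind, items in (("spacer", spacers), ("overlap", overlaps)):
                for adj in items:
                    adj_rows.append(
                        {"taxon": rec.accession, "kind": kind, "upstream": adj.upstream,
                         "downstream": adj.downstream, "length": adj.length}
                    )
        except ValueError as exc:
            logger.warning("%s: gene-order analysis failed: %s", rec.accession, exc)
    adjacency = pd.DataFrame(
        adj_rows, columns=["taxon", "kind", "upstream", "downstream", "length"]
    )

    manifest = {
        "package": "mitocodon",
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "inputs": {
            rec.accession: hashlib.sha256(rec.sequence.encode()).hexdigest()
            for rec in records
        },
        "n_genomes": len(records),
    }
    return ResultBundle(
        records=records, composition=composition, gene_bias=gene_bias,
        rscu_matrix=rscu_matrix, cluster=cluster, optimal_reports=optimal_reports,
        motif_hits=motif_hits, partitions=partitions, order_diffs=order_diffs,
        adjacency=adjacency, manifest=manifest,
    )


def run_full_analysis(config: RunConfig) -> ResultBundle:
    records = load_records(config.inputs)
    return analyze_records(records, config)


def write_reports(bundle: ResultBundle, outdir: str | Path) -> list[Path]:
    """Serialize the bundle as TSV/JSON files with fixed schemas."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    save_df(bundle.composition, "composition.tsv")
    save_df(bundle.gene_bias, "codon_bias.tsv")
    save_df(bundle.motif_hits, "motif_hits.tsv")
    save_df(bundle.adjacency, "spacers_overlaps.tsv")

    if bundle.rscu_matrix is not None:
        path = outdir / "rscu_matrix.tsv"
        bundle.rscu_matrix.round(4).to_csv(path, sep="\t", index_label="taxon")
        written.append(path)
    if bundle.cluster is not None:
        path = outdir / "cluster.newick"
        path.write_text(bundle.cluster.to_newick() + "\n")
        written.append(path)

    for taxon, report in bundle.optimal_reports.items():
        table = report.table.copy()
        table["optimal"] = ["*" if x else "" for x in table["is_optimal"]]
        table = table.drop(columns=["is_optimal"]).round(4)
        save_df(table, f"optimal_{taxon.replace('.', '_')}.tsv")

    partition_rows = []
    for taxon, part in bundle.partitions.items():
        for domain, (start, end) in zip(("TAS", "central", "CSB"), part.intervals):
            partition_rows.append(
                {"taxon": taxon, "domain": domain, "start": start, "end": end}
            )
    save_df(
        pd.DataFrame(partition_rows, columns=["taxon", "domain", "start", "end"]),
        "cr_partitions.tsv",
    )

    order_rows = []
    for taxon, diff in bundle.order_diffs.items():
        order_rows.append(
            {
                "taxon": taxon,
                "insertions": ";".join(diff.insertions),
                "deletions": ";".join(diff.deletions),
                "translocations": ";".join(diff.translocations),
            }
        )
    save_df(
        pd.DataFrame(order_rows, columns=["taxon", "insertions", "deletions", "translocations"]),
        "gene_order_diffs.tsv",
    )

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
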