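"""End-to-end orchestration: trim -> count -> filter -> cluster -> screen.

Each stage is a function that writes its tables to the output directory, so
stages are individually re-runnable (and the CLI subcommands compose to
byte-identical outputs of the orchestrated run); the run report records
per-stage row counts, parameters and wall-clock times.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .clustering import (Cluster, ClusterParams, greedy_cluster,
                         representatives, clusters_to_tsv)
from .counting import (Pool, count_unique, compute_rpm, filter_min_count,
                       pool_to_tsv)
from .io import (LibraryLayout, B02_LAYOUT, TrimStats, parse_reads, trim_pool,
                 write_sequences)
from .screen import (CandidateFilter, EnrichmentRecord, annotate_clusters,
                     candidates_to_fasta, heatmap_matrix, join_pools,
                     nontarget_only_records, records_to_frame, scatter_table,
                     screen_candidates)

__all__ = ["RunConfig", "RunReport", "EmptyPoolError", "run_screen",
           "trim_stage", "count_stage", "cluster_stage", "screen_stage"]

logger = logging.getLogger(__name__)


class EmptyPoolError(RuntimeError):
    """A pool ended up empty (no extractable reads, or none past the filter)."""


@dataclass
class RunConfig:
    """All knobs of one screen run; the defaults are the screen's canonical
    parameters (min count 8, radius 6, RPM floor 500, enrichment ceiling 0.5)."""

    target_reads: str | Path
    nontarget_reads: str | Path
    out_dir: str | Path
    layout: LibraryLayout = B02_LAYOUT
    read_format: str = "auto"
    max_mismatch: int = 0
    revcomp_scan: bool = False
    min_count: int = 8
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    candidate_filter: CandidateFilter = field(default_factory=CandidateFilter)
    pseudo_rpm: float = 0.0

    def __post_init__(self) -> None:
        if Path(self.target_reads) == Path(self.nontarget_reads):
            raise ValueError("target and nontarget read paths must differ")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class RunReport:
    """Machine-readable per-stage bookkeeping for one run."""

    version: str
    parameters: dict
    stages: dict = field(default_factory=dict)
    n_candidates: int = 0
    candidates: list = field(default_factory=list)

    def add_stage(self, name: str, seconds: float, **counts: int) -> None:
        self.stages[name] = {"wall_clock_s": round(seconds, 3), **counts}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def trim_stage(reads_path: str | Path, layout: LibraryLayout, out_dir: str | Path,
               label: str, read_format: str = "auto", max_mismatch: int = 0,
               revcomp_scan: bool = False) -> tuple[list[str], TrimStats]:
    """Parse reads and extract random regions; writes ``<label>.trimmed.txt``
    and ``<label>.trim_stats.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads = parse_reads(reads_path, format=read_format)
    sequences, stats = trim_pool(reads, layout, max_mismatch, revcomp_scan)
    stats.to_json(out_dir / f"{label}.trim_stats.json")
    write_sequences(sequences, out_dir / f"{label}.trimmed.txt")
    logger.info("trim[%s]: %d reads in, %d extracted, %d rejected",
                label, stats.n_input, stats.n_extracted, stats.n_rejected)
    if not sequences:
        raise EmptyPoolError(f"{label}: no read yielded a random-region sequence")
    return sequences, stats


def count_stage(sequences: list[str], label: str, out_dir: str | Path,
                min_count: int = 8) -> Pool:
    """Count unique species, compute RPM and apply the minimum-read filter;
    writes ``<label>.counts.tsv`` (unfiltered) and ``<label>.counts.filtered.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pool = compute_rpm(count_unique(sequences, label=label))
    pool_to_tsv(pool, out_dir / f"{label}.counts.tsv")
    filtered = filter_min_count(pool, min_count)
    pool_to_tsv(filtered, out_dir / f"{label}.counts.filtered.tsv")
    logger.info("count[%s]: %d unique, %d past min_count=%d",
                label, len(pool), len(filtered), min_count)
    if len(filtered) == 0:
        raise EmptyPoolError(f"{label}: no sequence reaches min_count={min_count}")
    return filtered


def cluster_stage(pool: Pool, params: ClusterParams,
                  out_dir: str | Path) -> list[Cluster]:
    """Greedy-cluster the (target) pool; writes ``<label>.clusters.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clusters = greedy_cluster(pool, params)
    clusters_to_tsv(clusters, out_dir / f"{pool.label}.clusters.tsv")
    logger.info("cluster[%s]: %d clusters over %d sequences",
                pool.label, len(clusters), len(pool))
    return clusters


def screen_stage(target: Pool, nontarget: Pool, clusters: list[Cluster],
                 candidate_filter: CandidateFilter, out_dir: str | Path,
                 pseudo_rpm: float = 0.0) -> list[EnrichmentRecord]:
    """Join pools, screen candidates and export the data products:
    ``enrichment.tsv``, ``scatter.tsv``, ``heatmap.tsv``, ``candidates.tsv``,
    ``candidates.fasta``. Returns the final candidate records."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reps = representatives(clusters)
    records = annotate_clusters(join_pools(target, nontarget), clusters)
    records_to_frame(records).to_csv(out_dir / "enrichment.tsv", sep="\t",
                                     index=False, float_format="%.6f")
    scatter = scatter_table(records, reps, candidate_filter)
    scatter.to_csv(out_dir / "scatter.tsv", sep="\t", index=False,
                   float_format="%.6f")
    heat = heatmap_matrix(records + nontarget_only_records(target, nontarget),
                          pseudo_rpm=pseudo_rpm,
                          target_label=target.label,
                          nontarget_label=nontarget.label)
    heat.to_csv(out_dir / "heatmap.tsv", sep="\t", float_format="%.6f")

    candidates = screen_candidates(records, reps, candidate_filter)
    records_to_frame(candidates).to_csv(out_dir / "candidates.tsv", sep="\t",
                                        index=False, float_format="%.6f")
    candidates_to_fasta(candidates, out_dir / "candidates.fasta")
    logger.info("screen: %d representatives above RPM floor, %d final candidates",
                len(scatter), len(candidates))
    return candidates


def run_screen(config: RunConfig) -> RunReport:
    """Run the whole screen; writes every intermediate and final table plus
    ``run_report.json``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__,
        parameters={
            "layout": asdict(config.layout),
            "max_mismatch": config.max_mismatch,
            "revcomp_scan": config.revcomp_scan,
            "min_count": config.min_count,
            "cluster": asdict(config.cluster_params),
            "filter": asdict(config.candidate_filter),
            "pseudo_rpm": config.pseudo_rpm,
        },
    )

    pools = {}
    for label, path in (("target", config.target_reads),
                        ("nontarget", config.nontarget_reads)):
        t0 = time.perf_counter()
        sequences, stats = trim_stage(path, config.layout, out_dir, label,
                                      config.read_format, config.max_mismatch,
                                      config.revcomp_scan)
        report.add_stage(f"trim_{label}", time.perf_counter() - t0,
                         n_input=stats.n_input, n_extracted=stats.n_extracted,
                         n_rejected=stats.n_rejected)
        t0 = time.perf_counter()
        pools[label] = count_stage(sequences, label, out_dir, config.min_count)
        report.add_stage(f"count_{label}", time.perf_counter() - t0,
                         n_unique=len(set(sequences)),
                         n_past_filter=len(pools[label]))

    t0 = time.perf_counter()
    clusters = cluster_stage(pools["target"], config.cluster_params, out_dir)
    report.add_stage("cluster", time.perf_counter() - t0,
                     n_clusters=len(clusters), n_sequences=len(pools["target"]))

    t0 = time.perf_counter()
    candidates = screen_stage(pools["target"], pools["nontarget"], clusters,
                              config.candidate_filter, out_dir, config.pseudo_rpm)
    scatter_rows = sum(1 for _ in open(out_dir / "scatter.tsv")) - 1
    report.add_stage("screen", time.perf_counter() - t0,
                     n_records=len(pools["target"]),
                     n_representatives_above_rpm=scatter_rows,
                     n_candidates=len(candidates))
    report.n_candidates = len(candidates)
    report.candidates = [rec.sequence for rec in candidates]
    report.to_json(out_dir / "run_report.json")
    return report
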