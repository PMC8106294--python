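"""Target-vs-counter enrichment screen and its exported data products.

The screen joins the target ("positive") pool against the counter-selection
("nontarget") pool. For a sequence with target-pool RPM x and nontarget-pool
RPM y, the enrichment ratio is y/x: values <= 0.5 mean the sequence is more
than twice as abundant in the target pool as in the counter pool. Final
candidates are cluster representatives with x strictly above the RPM floor and
y/x at or below the enrichment ceiling.

Exports: the candidate table, the per-representative scatter table
(x, y, ratio per family representative), and a log2 median-normalized RPM
matrix suitable for heatmap rendering and hierarchical clustering downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .clustering import Cluster
from .counting import Pool, SequenceCount

__all__ = [
    "EnrichmentRecord",
    "CandidateFilter",
    "join_pools",
    "nontarget_only_records",
    "annotate_clusters",
    "screen_candidates",
    "scatter_table",
    "heatmap_matrix",
    "records_to_frame",
    "candidates_to_fasta",
]


class EnrichmentRecord(NamedTuple):
    """One sequence's abundance in both pools plus the y/x ratio.

    ``enrichment`` is NaN when ``rpm_target`` is 0 (the ratio is undefined and
    such sequences are never candidates).
    """

    sequence: str
    rpm_target: float
    rpm_nontarget: float
    enrichment: float
    cluster_id: int | None = None
    is_representative: bool = False


@dataclass(frozen=True)
class CandidateFilter:
    """The two candidate thresholds, read literally from their printed form:
    the RPM floor is strict (> 500), the enrichment ceiling inclusive (<= 0.5).
    Both readings are switchable for sensitivity analysis."""

    min_rpm_target: float = 500.0
    max_enrichment: float = 0.5
    strict_rpm: bool = True
    inclusive_enrichment: bool = True

    def __post_init__(self) -> None:
        if self.min_rpm_target <= 0 or self.max_enrichment <= 0:
            raise ValueError("thresholds must be strictly positive")

    def passes_rpm(self, rpm_target: float) -> bool:
        return rpm_target > self.min_rpm_target if self.strict_rpm \
            else rpm_target >= self.min_rpm_target

    def passes_enrichment(self, enrichment: float) -> bool:
        if math.isnan(enrichment):
            return False
        return enrichment <= self.max_enrichment if self.inclusive_enrichment \
            else enrichment < self.max_enrichment


def _ratio(rpm_target: float, rpm_nontarget: float) -> float:
    return rpm_nontarget / rpm_target if rpm_target > 0 else float("nan")


def join_pools(target: Pool, nontarget: Pool) -> list[EnrichmentRecord]:
    """One enrichment record per sequence of the target pool, in rank order.

    Sequences absent from the nontarget pool get y = 0 (hence ratio 0, the
    strongest possible candidates). Sequences present only in the nontarget
    pool carry no ratio and are handled by :func:`nontarget_only_records`.
    """
    if target.label == nontarget.label:
        raise ValueError("target and nontarget pools carry the same label")
    return [
        EnrichmentRecord(r.sequence, r.rpm, nontarget.rpm_of(r.sequence),
                         _ratio(r.rpm, nontarget.rpm_of(r.sequence)))
        for r in sorted(target.records, key=lambda r: r.rank)
    ]


def nontarget_only_records(target: Pool, nontarget: Pool) -> list[EnrichmentRecord]:
    """Sequences seen only in the counter pool; excluded from candidacy but
    kept for the joint heatmap."""
    in_target = {r.sequence for r in target.records}
    return [
        EnrichmentRecord(r.sequence, 0.0, r.rpm, float("nan"))
        for r in sorted(nontarget.records, key=lambda r: r.rank)
        if r.sequence not in in_target
    ]


def annotate_clusters(records: Sequence[EnrichmentRecord],
                      clusters: Sequence[Cluster]) -> list[EnrichmentRecord]:
    """Attach cluster ids and representative flags from a target-pool clustering."""
    membership: dict[str, tuple[int, bool]] = {}
    for c in clusters:
        for member, _ in c.members:
            membership[member.sequence] = (c.cluster_id, member.sequence == c.seed.sequence)
    out = []
    for rec in records:
        cid, is_rep = membership.get(rec.sequence, (None, False))
        out.append(rec._replace(cluster_id=cid, is_representative=is_rep))
    return out


def screen_candidates(records: Sequence[EnrichmentRecord],
                      representatives: Sequence[SequenceCount],
                      filter: CandidateFilter = CandidateFilter()) -> list[EnrichmentRecord]:
    """Final candidates: cluster representatives above the RPM floor with the
    enrichment ratio at or below the ceiling, ordered by target RPM descending."""
    rep_seqs = {r.sequence for r in representatives}
    kept = [
        rec for rec in records
        if rec.sequence in rep_seqs
        and filter.passes_rpm(rec.rpm_target)
        and filter.passes_enrichment(rec.enrichment)
    ]
    return sorted(kept, key=lambda r: (-r.rpm_target, r.sequence))


def scatter_table(records: Sequence[EnrichmentRecord],
                  representatives: Sequence[SequenceCount],
                  filter: CandidateFilter = CandidateFilter()) -> pd.DataFrame:
    """Per-representative table behind the x-y scatter of the screen.

    One row per cluster representative passing the RPM floor; the
    ``is_candidate`` flag marks rows that also pass the enrichment ceiling.
    """
    rep_seqs = {r.sequence for r in representatives}
    rows = [
        {
            "sequence": rec.sequence,
            "rpm_target": rec.rpm_target,
            "rpm_nontarget": rec.rpm_nontarget,
            "enrichment": rec.enrichment,
            "cluster_id": rec.cluster_id,
            "is_candidate": filter.passes_enrichment(rec.enrichment),
        }
        for rec in records
        if rec.sequence in rep_seqs and filter.passes_rpm(rec.rpm_target)
    ]
    df = pd.DataFrame(rows, columns=["sequence", "rpm_target", "rpm_nontarget",
                                     "enrichment", "cluster_id", "is_candidate"])
    if len(df):
        df = df.sort_values(["rpm_target", "sequence"],
                            ascending=[False, True]).reset_index(drop=True)
    return df


def heatmap_matrix(records: Sequence[EnrichmentRecord],
                   pseudo_rpm: float = 0.0,
                   target_label: str = "target",
                   nontarget_label: str = "nontarget") -> pd.DataFrame:
    """log2 median-normalized RPM matrix, one row per sequence, one column per pool.

    Each column's values are log2((rpm + pseudo_rpm) / median over that
    column's included sequences of (rpm + pseudo_rpm)); the median is the
    midpoint of the two central order statistics for even n. With
    ``pseudo_rpm`` 0, sequences absent from a pool are excluded from that
    column (NaN); a positive pseudo count keeps every sequence in both columns.
    """
    if pseudo_rpm < 0:
        raise ValueError("pseudo_rpm must be non-negative")
    seqs = [r.sequence for r in records]
    data = pd.DataFrame(
        {
            target_label: [r.rpm_target for r in records],
            nontarget_label: [r.rpm_nontarget for r in records],
        },
        index=pd.Index(seqs, name="sequence"),
    )
    out = {}
    for col in data.columns:
        vals = data[col] + pseudo_rpm
        included = vals[vals > 0]
        if included.empty:
            raise ValueError(f"column {col!r}: no sequence with positive RPM")
        med = included.median()  # numpy/pandas median = midpoint convention
        out[col] = np.log2(vals.where(vals > 0) / med)
    return pd.DataFrame(out, index=data.index)


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=EnrichmentRecord._fields)
    df["cluster_id"] = df["cluster_id"].astype("Int64")
    return df


def candidates_to_fasta(candidates: Sequence[EnrichmentRecord], path: str | Path) -> None:
    """Candidate FASTA for downstream motif / secondary-structure tools."""
    with open(path, "w") as fh:
        for i, rec in enumerate(candidates, start=1):
            fh.write(f">candidate{i} rpm_target={rec.rpm_target:.2f} "
                     f"enrichment={rec.enrichment:.4f} cluster={rec.cluster_id}\n"
                     f"{rec.sequence}\n")
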