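"""Unique-species counting, reads-per-million normalization and the
minimum-read filter.

RPM (reads per million) is ``count / total_reads * 1e6`` where the denominator
is the sample's total trimmed read count *before* any abundance filtering, so
RPM values stay comparable across filter settings. The minimum-read filter
drops species seen fewer than ``min_count`` times (default 8): sequencing
singletons and near-singletons at typical SELEX depths are dominated by
amplification and sequencing noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "SequenceCount",
    "Pool",
    "count_unique",
    "compute_rpm",
    "filter_min_count",
    "pool_to_tsv",
    "pool_from_tsv",
    "pool_to_fasta",
]

logger = logging.getLogger(__name__)

POOL_COLUMNS = ["sequence", "count", "rpm", "rank"]


class SequenceCount(NamedTuple):
    """One unique sequence with its abundance in a pool."""

    sequence: str
    count: int
    rpm: float
    rank: int


@dataclass(frozen=True)
class Pool:
    """A sample's unique sequences with counts, RPM and abundance ranks.

    ``total_reads`` is the RPM denominator (total trimmed reads, pre-filter);
    it is preserved by :func:`filter_min_count` so dropping low-count species
    never inflates the RPM of survivors.
    """

    label: str
    total_reads: int
    records: tuple[SequenceCount, ...]
    min_count_applied: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def rpm_of(self, sequence: str) -> float:
        """RPM of ``sequence``, 0.0 when absent from the pool."""
        return self._rpm_index().get(sequence, 0.0)

    def _rpm_index(self) -> dict[str, float]:
        cached = getattr(self, "_rpm_cache", None)
        if cached is None:
            cached = {r.sequence: r.rpm for r in self.records}
            object.__setattr__(self, "_rpm_cache", cached)
        return cached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=POOL_COLUMNS)


def _rank_records(items: Iterable[tuple[str, int]]) -> tuple[SequenceCount, ...]:
    # count descending, lexicographic tie-break: deterministic across runs.
    ordered = sorted(items, key=lambda kv: (-kv[1], kv[0]))
    return tuple(
        SequenceCount(seq, cnt, float("nan"), rank)
        for rank, (seq, cnt) in enumerate(ordered, start=1)
    )


def count_unique(sequences: Sequence[str], label: str) -> Pool:
    """Collapse a list of trimmed sequences into a ranked pool of unique species.

    Ranks are assigned by count descending with lexicographic tie-break.
    RPM is left unset until :func:`compute_rpm`.
    """
    if len(sequences) == 0:
        raise ValueError(f"pool {label!r}: empty input, a pool with zero reads has no RPM")
    counts: dict[str, int] = {}
    for seq in sequences:
        counts[seq] = counts.get(seq, 0) + 1
    return Pool(label=label, total_reads=len(sequences),
                records=_rank_records(counts.items()))


def compute_rpm(pool: Pool) -> Pool:
    """Fill in reads-per-million: ``count / total_reads * 1e6``."""
    if pool.total_reads <= 0:
        raise ValueError(f"pool {pool.label!r}: total_reads must be positive")
    scale = 1e6 / pool.total_reads
    records = tuple(r._replace(rpm=r.count * scale) for r in pool.records)
    return replace(pool, records=records)


def filter_min_count(pool: Pool, min_count: int = 8) -> Pool:
    """Drop species with count < ``min_count``; keep RPM denominators intact.

    Ranks are recomputed over the survivors; RPM values are unchanged.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    survivors = [r for r in pool.records if r.count >= min_count]
    if not survivors:
        logger.warning("pool %r: no sequence reaches %d reads, pool is empty after filtering",
                       pool.label, min_count)
    records = tuple(r._replace(rank=i) for i, r in enumerate(survivors, start=1))
    return replace(pool, records=records, min_count_applied=min_count)


def pool_to_tsv(pool: Pool, path: str | Path) -> None:
    pool.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def pool_from_tsv(path: str | Path, label: str, total_reads: int | None = None,
                  min_count_applied: int = 0) -> Pool:
    """Load a pool TSV written by :func:`pool_to_tsv`.

    ``total_reads`` defaults to the sum of counts, which is only correct for
    unfiltered pools; pass the true trimmed total when reloading filtered ones.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    records = tuple(
        SequenceCount(row.sequence, int(row.count), float(row.rpm), int(row.rank))
        for row in df.itertuples(index=False)
    )
    total = int(df["count"].sum()) if total_reads is None else total_reads
    return Pool(label=label, total_reads=total, records=records,
                min_count_applied=min_count_applied)


def pool_to_fasta(pool: Pool, path: str | Path) -> None:
    """FASTA dialect with ``>rank-count-rpm`` headers, as common SELEX tools emit."""
    with open(path, "w") as fh:
        for r in pool.records:
            fh.write(f">{r.rank}-{r.count}-{r.rpm:.2f}\n{r.sequence}\n")
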