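"""Greedy abundance-ordered Levenshtein clustering of a pool.

Mutational families in an enriched SELEX pool are clouds of point variants
around a dominant sequence. The clustering walks the pool in abundance-rank
order: each not-yet-assigned sequence seeds a new cluster and absorbs every
remaining sequence within the edit-distance radius of that seed. Membership is
to the seed, not transitive, so chains do not merge clusters. The seed is by
construction the most abundant member and serves as the family representative.

Distances are unit-cost Levenshtein (substitutions, insertions, deletions),
computed with edlib; the radius bound doubles as an early-exit cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd

from .counting import Pool, SequenceCount

__all__ = [
    "ClusterParams",
    "Cluster",
    "edit_distance",
    "greedy_cluster",
    "representatives",
    "clusters_to_frame",
    "clusters_to_tsv",
    "clusters_from_tsv",
]

CLUSTER_COLUMNS = ["sequence", "count", "rpm", "rank", "cluster_id",
                   "distance_to_seed", "is_seed"]


@dataclass(frozen=True)
class ClusterParams:
    """Clustering radius.

    ``inclusive=True`` assigns at distance <= ``max_distance`` (the common
    SELEX-tool convention); ``inclusive=False`` uses strict < ``max_distance``.
    """

    max_distance: int = 6
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be non-negative")

    @property
    def threshold(self) -> int:
        """Largest distance that joins a cluster (may be -1: nothing joins)."""
        return self.max_distance if self.inclusive else self.max_distance - 1


def edit_distance(a: str, b: str, max_distance: int | None = None) -> int:
    """Levenshtein distance between two sequences.

    With ``max_distance`` set, computation may stop early once the distance
    provably exceeds it and -1 is returned (same contract as edlib's ``k``).
    """
    if a == b:
        return 0
    k = -1 if max_distance is None else max_distance
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


@dataclass
class Cluster:
    """One mutational family: a seed plus members within the radius."""

    cluster_id: int
    seed: SequenceCount
    members: list[tuple[SequenceCount, int]] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(m.count for m, _ in self.members)

    @property
    def size(self) -> int:
        return len(self.members)


def greedy_cluster(pool: Pool, params: ClusterParams = ClusterParams()) -> list[Cluster]:
    """Partition a ranked pool into clusters by greedy seed absorption.

    Records are visited in rank order (count descending, lexicographic ties);
    every record belongs to exactly one cluster and cluster ids follow seed
    rank, so cluster 1 is seeded by the most abundant sequence.
    """
    records = sorted(pool.records, key=lambda r: r.rank)
    n = len(records)
    assigned = [False] * n
    clusters: list[Cluster] = []
    thr = params.threshold
    for i, rec in enumerate(records):
        if assigned[i]:
            continue
        assigned[i] = True
        cluster = Cluster(cluster_id=len(clusters) + 1, seed=rec, members=[(rec, 0)])
        if thr >= 0:
            for j in range(i + 1, n):
                if assigned[j]:
                    continue
                d = edit_distance(rec.sequence, records[j].sequence, max_distance=thr)
                if 0 <= d <= thr:
                    assigned[j] = True
                    cluster.members.append((records[j], d))
        clusters.append(cluster)
    return clusters


def representatives(clusters: list[Cluster]) -> list[SequenceCount]:
    """Each cluster's seed (its highest-count = highest-RPM member), by cluster id."""
    return [c.seed for c in sorted(clusters, key=lambda c: c.cluster_id)]


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    rows = [
        (m.sequence, m.count, m.rpm, m.rank, c.cluster_id, d, m.sequence == c.seed.sequence)
        for c in clusters
        for m, d in c.members
    ]
    df = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return df.sort_values(["cluster_id", "distance_to_seed", "rank"]).reset_index(drop=True)


def clusters_to_tsv(clusters: list[Cluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False, float_format="%.6f")


def clusters_from_tsv(path: str | Path) -> list[Cluster]:
    """Reload clusters written by :func:`clusters_to_tsv` (for stage-wise runs)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    clusters: list[Cluster] = []
    for cid, grp in df.groupby("cluster_id", sort=True):
        members = [
            (SequenceCount(r.sequence, int(r.count), float(r.rpm), int(r.rank)),
             int(r.distance_to_seed))
            for r in grp.itertuples(index=False)
        ]
        seeds = [m for (m, d), flag in zip(members, grp["is_seed"]) if flag]
        if len(seeds) != 1:
            raise ValueError(f"cluster {cid}: expected exactly one seed row")
        clusters.append(Cluster(cluster_id=int(cid), seed=seeds[0], members=members))
    return clusters
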