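"""Independent reference implementations used only to check the package.

Deliberately naive: the textbook full-table Levenshtein DP and a direct
transcription of the greedy clustering definition on top of it. Nothing here
imports the package's distance or clustering code.
"""

from __future__ import annotations


def dp_edit_distance(a: str, b: str) -> int:
    """Full O(len(a)*len(b)) Levenshtein dynamic program."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,                       # delete a[i-1]
                cur[j - 1] + 1,                    # insert b[j-1]
                prev[j - 1] + (a[i - 1] != b[j - 1]),  # substitute/match
            )
        prev = cur
    return prev[m]


def brute_force_cluster(
    ranked_sequences: list[str], max_distance: int, inclusive: bool = True
) -> list[list[tuple[str, int]]]:
    """Greedy abundance-ordered clustering, written directly from its
    definition: walk sequences in rank order, the first unassigned sequence
    seeds a cluster and absorbs all remaining unassigned sequences within the
    radius of that seed. Returns per cluster the (sequence, distance) members,
    seed first."""
    threshold = max_distance if inclusive else max_distance - 1
    unassigned = list(ranked_sequences)
    clusters: list[list[tuple[str, int]]] = []
    while unassigned:
        seed = unassigned.pop(0)
        members = [(seed, 0)]
        rest = []
        for seq in unassigned:
            d = dp_edit_distance(seed, seq)
            if d <= threshold:
                members.append((seq, d))
            else:
                rest.append(seq)
        unassigned = rest
        clusters.append(members)
    return clusters
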