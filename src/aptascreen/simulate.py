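"""Synthetic paired SELEX pool generator with known ground truth.

A terminal selection round is modeled as a mixture: a handful of planted
mutational families (each a designed 40-mer seed emitted through an i.i.d.
per-base substitution channel) over a uniform random background drawn from the
full 4^40 library space. Each family has its own share of the target pool and
of the counter-selection pool, so the family's expected enrichment ratio
(counter share / target share) can be placed on either side of the screen's
ceiling. Background 40-mers essentially never recur at desk-scale depths, so
the minimum-read filter removes them and the planted families are the only
structure the pipeline should find — which is what makes recovery quantifiable.

Only terminal-pool composition is modeled; multi-round selection dynamics
(binding kinetics, amplification bias) are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterParams, edit_distance
from .io import LibraryLayout, B02_LAYOUT
from .screen import EnrichmentRecord

__all__ = [
    "FamilySpec",
    "PoolSpec",
    "RecoveryResult",
    "random_library_sequence",
    "mutate",
    "generate_pools",
    "evaluate_recovery",
    "default_pool_spec",
    "pool_spec_to_yaml",
    "pool_spec_from_yaml",
]

_BASES = "ACGT"
_ENCODE = {b: i for i, b in enumerate(_BASES)}
_ASCII = np.frombuffer(_BASES.encode(), dtype=np.uint8)

MANIFEST_COLUMNS = [
    "family_id", "seed_sequence", "expected_candidate",
    "count_target", "count_nontarget",
    "seed_count_target", "seed_count_nontarget",
    "seed_rpm_target", "seed_rpm_nontarget", "realized_enrichment",
]


@dataclass(frozen=True)
class FamilySpec:
    """One planted mutational family.

    Fractions are the family's expected share of reads in each pool;
    ``substitution_rate`` is the per-base substitution probability applied
    independently to every emitted copy of the seed (so the exact seed itself
    is emitted with probability ``(1 - rate)^L``). ``expected_candidate`` is
    the truth label under the screen's default thresholds. ``indel_rate``
    (default 0, stress tests only) adds per-base insertion/deletion noise.
    """

    family_id: str
    seed_sequence: str
    target_fraction: float
    nontarget_fraction: float
    substitution_rate: float = 0.02
    expected_candidate: bool = True
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("target_fraction", "nontarget_fraction", "substitution_rate",
                     "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.family_id}: {name}={v} outside [0, 1]")
        if set(self.seed_sequence) - set(_BASES):
            raise ValueError(f"{self.family_id}: seed has non-ACGT characters")


@dataclass(frozen=True)
class PoolSpec:
    """Full recipe for one paired target/nontarget pool simulation.

    ``rng_seed`` is mandatory: the output (read files and manifest) is a pure
    function of the spec.
    """

    layout: LibraryLayout = B02_LAYOUT
    n_reads_target: int = 50_000
    n_reads_nontarget: int = 50_000
    families: tuple[FamilySpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads_target <= 0 or self.n_reads_nontarget <= 0:
            raise ValueError("read counts must be positive")
        for fam in self.families:
            if len(fam.seed_sequence) != self.layout.random_length:
                raise ValueError(
                    f"{fam.family_id}: seed length {len(fam.seed_sequence)} "
                    f"!= layout random_length {self.layout.random_length}")
        for attr in ("target_fraction", "nontarget_fraction"):
            total = sum(getattr(f, attr) for f in self.families)
            if total > 1.0 + 1e-12:
                raise ValueError(f"family {attr}s sum to {total} > 1")

    def background_fraction(self, pool: str) -> float:
        attr = "target_fraction" if pool == "target" else "nontarget_fraction"
        return 1.0 - sum(getattr(f, attr) for f in self.families)


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENCODE[b] for b in seq], dtype=np.uint8)


def _decode_rows(arr: np.ndarray) -> list[str]:
    chars = _ASCII[arr]
    return [row.tobytes().decode() for row in chars]


def random_library_sequence(rng: np.random.Generator, layout: LibraryLayout) -> str:
    """One i.i.d. uniform draw from {A,C,G,T}^random_length."""
    return _decode_rows(rng.integers(0, 4, size=(1, layout.random_length),
                                     dtype=np.uint8))[0]


def _substitute(block: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-base substitution to a uniformly chosen *different* base."""
    if rate <= 0.0:
        return block
    mask = rng.random(block.shape) < rate
    shift = rng.integers(1, 4, size=block.shape, dtype=np.uint8)
    return np.where(mask, (block + shift) % 4, block)


def mutate(sequence: str, substitution_rate: float, rng: np.random.Generator) -> str:
    """Apply the substitution channel to one sequence (length preserved)."""
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate outside [0, 1]")
    block = _substitute(_encode(sequence)[None, :], substitution_rate, rng)
    return _decode_rows(block)[0]


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for ch in seq:
        r = rng.random()
        if r < rate / 2:          # deletion
            continue
        if r < rate:              # insertion before the base
            out.append(_BASES[rng.integers(0, 4)])
        out.append(ch)
    return "".join(out)


def _generate_pool(spec: PoolSpec, pool: str, n_reads: int,
                   rng: np.random.Generator) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Emit one pool's random-region sequences.

    Returns (inserts, per-family origin read counts, per-family exact-seed counts).
    """
    attr = "target_fraction" if pool == "target" else "nontarget_fraction"
    probs = [getattr(f, attr) for f in spec.families]
    probs.append(spec.background_fraction(pool))
    n_fam = len(spec.families)
    origins = rng.choice(n_fam + 1, size=n_reads, p=probs)

    L = spec.layout.random_length
    inserts: list[str | None] = [None] * n_reads
    fam_counts = np.zeros(n_fam, dtype=np.int64)
    seed_counts = np.zeros(n_fam, dtype=np.int64)
    for k, fam in enumerate(spec.families):
        idx = np.flatnonzero(origins == k)
        fam_counts[k] = len(idx)
        if len(idx) == 0:
            continue
        seed_arr = _encode(fam.seed_sequence)
        block = _substitute(np.tile(seed_arr, (len(idx), 1)),
                            fam.substitution_rate, rng)
        seed_counts[k] = int((block == seed_arr).all(axis=1).sum())
        seqs = _decode_rows(block)
        if fam.indel_rate > 0:
            seqs = [_apply_indels(s, fam.indel_rate, rng) for s in seqs]
            seed_counts[k] = sum(s == fam.seed_sequence for s in seqs)
        for i, s in zip(idx, seqs):
            inserts[i] = s
    bg_idx = np.flatnonzero(origins == n_fam)
    if len(bg_idx):
        bg = rng.integers(0, 4, size=(len(bg_idx), L), dtype=np.uint8)
        for i, s in zip(bg_idx, _decode_rows(bg)):
            inserts[i] = s
    return inserts, fam_counts, seed_counts  # type: ignore[return-value]


def _write_reads(inserts: Sequence[str], layout: LibraryLayout, path: Path,
                 format: str, label: str) -> None:
    five, three = layout.five_prime_const, layout.three_prime_const
    with open(path, "w") as fh:
        if format == "fasta":
            for i, ins in enumerate(inserts, start=1):
                fh.write(f">{label}_{i}\n{five}{ins}{three}\n")
        elif format == "fastq":
            for i, ins in enumerate(inserts, start=1):
                read = f"{five}{ins}{three}"
                fh.write(f"@{label}_{i}\n{read}\n+\n{'I' * len(read)}\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def generate_pools(spec: PoolSpec, out_dir: str | Path,
                   format: str = "fastq") -> tuple[Path, Path, pd.DataFrame]:
    """Write the target and nontarget read files plus the truth manifest.

    Fully determined by ``spec`` (including ``rng_seed``). The manifest
    records each family's realized origin read counts, exact-seed counts, the
    seed's realized RPM in both pools and the realized enrichment ratio —
    i.e. exactly the quantities the screen's thresholds act on.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    ext = "fa" if format == "fasta" else "fq"
    paths, rows = {}, None
    fam_counts, seed_counts = {}, {}
    for pool, n_reads in (("target", spec.n_reads_target),
                          ("nontarget", spec.n_reads_nontarget)):
        inserts, fc, sc = _generate_pool(spec, pool, n_reads, rng)
        fam_counts[pool], seed_counts[pool] = fc, sc
        paths[pool] = out_dir / f"{pool}.{ext}"
        _write_reads(inserts, spec.layout, paths[pool], format, pool)

    rows = []
    for k, fam in enumerate(spec.families):
        rpm_t = seed_counts["target"][k] / spec.n_reads_target * 1e6
        rpm_n = seed_counts["nontarget"][k] / spec.n_reads_nontarget * 1e6
        rows.append({
            "family_id": fam.family_id,
            "seed_sequence": fam.seed_sequence,
            "expected_candidate": fam.expected_candidate,
            "count_target": int(fam_counts["target"][k]),
            "count_nontarget": int(fam_counts["nontarget"][k]),
            "seed_count_target": int(seed_counts["target"][k]),
            "seed_count_nontarget": int(seed_counts["nontarget"][k]),
            "seed_rpm_target": rpm_t,
            "seed_rpm_nontarget": rpm_n,
            "realized_enrichment": rpm_n / rpm_t if rpm_t > 0 else float("nan"),
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "truth_manifest.tsv", sep="\t", index=False)
    return paths["target"], paths["nontarget"], manifest


class RecoveryResult(NamedTuple):
    precision: float
    recall: float
    assignments: pd.DataFrame


def evaluate_recovery(candidates: Sequence[EnrichmentRecord],
                      truth: pd.DataFrame,
                      params: ClusterParams = ClusterParams()) -> RecoveryResult:
    """Score pipeline candidates against the planted truth.

    A candidate is assigned to the nearest planted family whose seed lies
    within the clustering radius. Precision counts candidates assigned to a
    family that should pass the screen (a candidate matching a planted family
    that should *fail* is a screen false positive); recall counts
    expected-candidate families recovered by at least one candidate.
    """
    thr = params.threshold  # -1 when the radius admits nothing
    rows = []
    matched_expected: set[str] = set()
    n_true_positive = 0
    for cand in candidates:
        best_id, best_d, best_expected = None, None, False
        for fam in truth.itertuples(index=False) if thr >= 0 else ():
            d = edit_distance(cand.sequence, fam.seed_sequence,
                              max_distance=thr)
            if d >= 0 and (best_d is None or d < best_d):
                best_id, best_d, best_expected = fam.family_id, d, bool(fam.expected_candidate)
        rows.append({"sequence": cand.sequence, "family_id": best_id,
                     "distance_to_seed": best_d, "family_expected": best_expected})
        if best_id is not None and best_expected:
            matched_expected.add(best_id)
            n_true_positive += 1
    expected_ids = set(truth.loc[truth["expected_candidate"], "family_id"])
    precision = n_true_positive / len(candidates) if candidates else 1.0
    recall = len(matched_expected & expected_ids) / len(expected_ids) if expected_ids else 1.0
    assignments = pd.DataFrame(rows, columns=["sequence", "family_id",
                                              "distance_to_seed", "family_expected"])
    return RecoveryResult(precision, recall, assignments)


# --- canonical study conditions -------------------------------------------

_DEFAULT_FAMILY_TABLE = [
    # family_id, target_fraction, nontarget_fraction, expected_candidate
    ("fam1", 0.12, 0.012, True),    # dominant, ~10x enriched
    ("fam2", 0.05, 0.010, True),    # ~5x enriched
    ("fam3", 0.02, 0.002, True),    # mid-abundance, ~10x enriched
    ("fam4", 0.008, 0.001, True),   # low but >2x above both thresholds
    ("fam5", 0.06, 0.060, False),   # abundant but unenriched (ratio ~1)
    ("fam6", 0.01, 0.020, False),   # counter-enriched (ratio ~2)
    ("fam7", 0.0005, 0.0005, False),  # below the RPM floor by >2x
]

_MIN_SEED_SEPARATION = 16  # > 2x clustering radius: planted clouds cannot merge


def default_pool_spec(rng_seed: int, n_reads: int = 50_000,
                      substitution_rate: float = 0.02,
                      layout: LibraryLayout = B02_LAYOUT) -> PoolSpec:
    """The canonical simulated study: 50,000 reads per pool, substitution rate
    0.02, seven heavy-tailed families — four clearing both default screen
    thresholds with at least 2-fold margins, two failing the enrichment
    ceiling, one failing the RPM floor.

    Family seeds are drawn from the given seed with pairwise edit distance
    >= 16 so no two planted clouds can fall in one cluster.
    """
    rng = np.random.default_rng(rng_seed)
    seeds: list[str] = []
    while len(seeds) < len(_DEFAULT_FAMILY_TABLE):
        cand = random_library_sequence(rng, layout)
        if all(edit_distance(cand, s) >= _MIN_SEED_SEPARATION for s in seeds):
            seeds.append(cand)
    families = tuple(
        FamilySpec(family_id=fid, seed_sequence=seed,
                   target_fraction=tf, nontarget_fraction=nf,
                   substitution_rate=substitution_rate, expected_candidate=exp)
        for (fid, tf, nf, exp), seed in zip(_DEFAULT_FAMILY_TABLE, seeds)
    )
    return PoolSpec(layout=layout, n_reads_target=n_reads,
                    n_reads_nontarget=n_reads, families=families,
                    rng_seed=rng_seed)


# --- YAML round-trip ------------------------------------------------------

def pool_spec_to_yaml(spec: PoolSpec, path: str | Path) -> None:
    doc = {
        "layout": asdict(spec.layout),
        "n_reads_target": spec.n_reads_target,
        "n_reads_nontarget": spec.n_reads_nontarget,
        "rng_seed": spec.rng_seed,
        "families": [asdict(f) for f in spec.families],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def pool_spec_from_yaml(path: str | Path) -> PoolSpec:
    doc = yaml.safe_load(Path(path).read_text())
    if "rng_seed" not in doc:
        raise ValueError("pool spec must set rng_seed explicitly")
    return PoolSpec(
        layout=LibraryLayout(**doc["layout"]),
        n_reads_target=doc["n_reads_target"],
        n_reads_nontarget=doc["n_reads_nontarget"],
        families=tuple(FamilySpec(**f) for f in doc.get("families", [])),
        rng_seed=doc["rng_seed"],
    )
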