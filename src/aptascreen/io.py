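"""Read parsing and random-region extraction.

A SELEX library read is ``<accessory><5' constant><random region><3' constant><accessory>``.
Everything upstream of the 5' constant region (barcode, adaptor, T7 promoter
remnants) and downstream of the 3' constant region is accessory sequence; the
pipeline anchors on the two constant regions and keeps only the randomized
insert between them, so accessory removal falls out of the anchoring itself.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "RawRead",
    "LibraryLayout",
    "B02_LAYOUT",
    "TrimStats",
    "Rejection",
    "parse_reads",
    "extract_random_region",
    "trim_pool",
    "reverse_complement",
    "write_sequences",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """One sequencing read. Quality is carried but never interpreted."""

    read_id: str
    bases: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.bases)}"
            )


@dataclass(frozen=True)
class LibraryLayout:
    """Fixed flanks and randomized-insert length of a combinatorial library.

    ``random_length`` is the designed insert length in nt; extraction keeps
    inserts within ``random_length ± length_tolerance``.
    """

    five_prime_const: str
    three_prime_const: str
    random_length: int
    length_tolerance: int = 0

    def __post_init__(self) -> None:
        if not self.five_prime_const or not self.three_prime_const:
            raise ValueError("constant regions must be non-empty")
        if self.random_length <= 0:
            raise ValueError("random_length must be positive")
        if self.length_tolerance < 0:
            raise ValueError("length_tolerance must be non-negative")


#: Layout of the B02 RNA library used for GPCR-VLP selections:
#: 5'-GTACGCTAGGCGTTAGTCTC-[N40]-ATCGTACGACGGTCGTACCC-3'.
B02_LAYOUT = LibraryLayout(
    five_prime_const="GTACGCTAGGCGTTAGTCTC",
    three_prime_const="ATCGTACGACGGTCGTACCC",
    random_length=40,
)


class Rejection(enum.Enum):
    """Why a read yielded no random-region sequence."""

    NO_ANCHOR = "no_anchor"
    LENGTH = "length"
    AMBIGUOUS_BASE = "ambiguous_base"


@dataclass
class TrimStats:
    """Bookkeeping for one trimming pass; every read lands in exactly one tally."""

    n_input: int = 0
    n_extracted: int = 0
    n_rejected_no_anchor: int = 0
    n_rejected_length: int = 0
    n_rejected_ambiguous_base: int = 0
    length_histogram: Counter = field(default_factory=Counter)

    def record(self, outcome: str | Rejection) -> None:
        self.n_input += 1
        if isinstance(outcome, Rejection):
            if outcome is Rejection.NO_ANCHOR:
                self.n_rejected_no_anchor += 1
            elif outcome is Rejection.LENGTH:
                self.n_rejected_length += 1
            else:
                self.n_rejected_ambiguous_base += 1
        else:
            self.n_extracted += 1
            self.length_histogram[len(outcome)] += 1

    @property
    def n_rejected(self) -> int:
        return (
            self.n_rejected_no_anchor
            + self.n_rejected_length
            + self.n_rejected_ambiguous_base
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_extracted": self.n_extracted,
            "n_rejected_no_anchor": self.n_rejected_no_anchor,
            "n_rejected_length": self.n_rejected_length,
            "n_rejected_ambiguous_base": self.n_rejected_ambiguous_base,
            "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                sigil = line[0]
                break
        else:
            raise ValueError(f"{path}: empty file, cannot detect format")
    if sigil == ">":
        return "fasta"
    if sigil == "@":
        return "fastq"
    raise ValueError(f"{path}: unrecognized leading character {sigil!r}")


def parse_reads(path: str | Path, format: str = "auto") -> Iterator[RawRead]:
    """Stream reads from a FASTA or FASTQ file in file order.

    Bases are uppercased and U is mapped to T (the libraries are RNA but all
    downstream logic works in DNA alphabet). Malformed records raise a
    ``ValueError`` naming the 0-based index of the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")

    index = 0
    with open(path) as fh:
        try:
            if fmt == "fasta":
                for title, seq in SimpleFastaParser(fh):
                    yield RawRead(title.split()[0] if title else f"read{index}",
                                  seq.upper().replace("U", "T"))
                    index += 1
            else:
                for title, seq, qual in FastqGeneralIterator(fh):
                    yield RawRead(title.split()[0] if title else f"read{index}",
                                  seq.upper().replace("U", "T"), qual)
                    index += 1
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record at index {index}: {exc}") from exc


def _find_approx(haystack: str, needle: str, start: int, max_mismatch: int) -> int:
    """Leftmost start position of ``needle`` in ``haystack[start:]`` allowing up
    to ``max_mismatch`` substitutions (no indels); -1 when absent."""
    if max_mismatch == 0:
        return haystack.find(needle, start)
    n, m = len(haystack), len(needle)
    for pos in range(start, n - m + 1):
        mismatches = 0
        for a, b in zip(haystack[pos : pos + m], needle):
            if a != b:
                mismatches += 1
                if mismatches > max_mismatch:
                    break
        else:
            return pos
    return -1


def extract_random_region(
    read: RawRead,
    layout: LibraryLayout,
    max_mismatch: int = 0,
    revcomp_scan: bool = False,
) -> str | Rejection:
    """Extract the randomized insert between the two constant-region anchors.

    Anchors match as substrings with at most ``max_mismatch`` substitutions
    each (leftmost 5' anchor, then leftmost 3' anchor after it). The insert is
    accepted when its length is within ``random_length ± length_tolerance``
    and it contains no N; otherwise a categorized :class:`Rejection` is
    returned (rejection is a value, not an error). With ``revcomp_scan`` the
    reverse complement is tried when forward anchoring fails.
    """
    bases = read.bases
    p5 = _find_approx(bases, layout.five_prime_const, 0, max_mismatch)
    if p5 >= 0:
        insert_start = p5 + len(layout.five_prime_const)
        p3 = _find_approx(bases, layout.three_prime_const, insert_start, max_mismatch)
        if p3 >= 0:
            insert = bases[insert_start:p3]
            if abs(len(insert) - layout.random_length) > layout.length_tolerance:
                return Rejection.LENGTH
            if "N" in insert:
                return Rejection.AMBIGUOUS_BASE
            return insert
    if revcomp_scan:
        rc = RawRead(read.read_id, reverse_complement(bases))
        return extract_random_region(rc, layout, max_mismatch, revcomp_scan=False)
    return Rejection.NO_ANCHOR


def trim_pool(
    reads: Iterable[RawRead],
    layout: LibraryLayout,
    max_mismatch: int = 0,
    revcomp_scan: bool = False,
) -> tuple[list[str], TrimStats]:
    """Extract the random region from every read, preserving input order."""
    stats = TrimStats()
    extracted: list[str] = []
    for read in reads:
        outcome = extract_random_region(read, layout, max_mismatch, revcomp_scan)
        stats.record(outcome)
        if not isinstance(outcome, Rejection):
            extracted.append(outcome)
    return extracted, stats


def write_sequences(sequences: Iterable[str], path: str | Path, fasta: bool = False) -> None:
    """Write trimmed sequences one per line, or as FASTA with running ids."""
    with open(path, "w") as fh:
        if fasta:
            for i, seq in enumerate(sequences, start=1):
                fh.write(f">seq{i}\n{seq}\n")
        else:
            for seq in sequences:
                fh.write(seq + "\n")
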