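"""Reading merged amplicon reads and extracting the peptide-coding region.

The display construct places the 33-nt peptide-coding insert between two
fixed amplicon flanks.  This module parses merged paired-end reads
(FASTQ or FASTA), locates both flanks and returns the in-between region;
reads lacking either flank are discarded with a reason code, mirroring
standard adapter-trimming behaviour.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, TextIO, Union

from Bio import SeqIO

__all__ = [
    "MergedRead",
    "FlankSpec",
    "CodingRegion",
    "Discard",
    "TrimStats",
    "read_merged_reads",
    "trim_flanks",
    "trim_reads",
    "find_with_mismatches",
    "write_fasta",
]

# Fixed amplicon flanks bordering the peptide-coding region, with the six
# sample-index (N6) bases stripped so indexing never affects matching.
DEFAULT_FIVE_PRIME = "ACCGCAGGTACTTCCGTAGCTGGCCAGTCTGGCCAG"
DEFAULT_THREE_PRIME = "GGAGGGCAGTCTGGGCAGTCTGGTGACTACAACAAAA"

_READ_ALPHABET = frozenset("ACGTN")
_DNA_ALPHABET = frozenset("ACGT")

DiscardReason = Literal["missing-5prime", "missing-3prime", "empty-insert"]


@dataclass(frozen=True)
class MergedRead:
    """One merged paired-end read.

    quality is carried for provenance but never used downstream: the
    pipeline operates on already merged reads and trusts the merger.
    """

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - _READ_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A,C,G,T,N)"
            )


@dataclass(frozen=True)
class FlankSpec:
    """Fixed 5'/3' flanks delimiting the coding region.

    max_mismatches is the per-flank Hamming tolerance (no indels).
    The default of 0 (exact matching) is conservative and reproducible.
    """

    five_prime_fixed: str = DEFAULT_FIVE_PRIME
    three_prime_fixed: str = DEFAULT_THREE_PRIME
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.five_prime_fixed or not self.three_prime_fixed:
            raise ValueError("flank sequences must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class CodingRegion:
    """The DNA strictly between the two flank matches."""

    read_id: str
    dna: str


@dataclass(frozen=True)
class Discard:
    """Signal that a read was dropped during trimming, with the reason."""

    read_id: str
    reason: DiscardReason


@dataclass
class TrimStats:
    """Per-run tally of kept and discarded reads."""

    total: int = 0
    kept: int = 0
    by_reason: dict = field(default_factory=dict)

    @property
    def discarded(self) -> int:
        return self.total - self.kept

    @property
    def discard_fraction(self) -> float:
        return self.discarded / self.total if self.total else 0.0

    def log_line(self, sample: str = "") -> str:
        reasons = ", ".join(f"{k}={v}" for k, v in sorted(self.by_reason.items()))
        prefix = f"[{sample}] " if sample else ""
        return (
            f"{prefix}trim: total={self.total} kept={self.kept} "
            f"discarded={self.discarded} ({self.discard_fraction:.4f}) {reasons}"
        )


def read_merged_reads(
    path: Union[str, Path],
    format: Literal["fastq", "fasta", "auto"] = "auto",
) -> Iterator[MergedRead]:
    """Stream merged reads from a FASTQ or FASTA file, order preserved.

    With format="auto" the format is detected from the first character
    ('@' -> FASTQ, '>' -> FASTA).  Empty files yield an empty stream.
    Malformed records raise ValueError naming the record index.
    """
    path = Path(path)
    fmt = format
    if fmt == "auto":
        with open(path) as handle:
            first = handle.read(1)
        if first == "":
            return
        fmt = "fastq" if first == "@" else "fasta"
        if first not in "@>":
            raise ValueError(f"{path}: cannot auto-detect format (starts with {first!r})")

    parser = SeqIO.parse(str(path), fmt)
    index = 0
    while True:
        try:
            record = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} record at index {index}: {exc}") from exc
        quality = None
        if fmt == "fastq":
            phred = record.letter_annotations.get("phred_quality", [])
            quality = "".join(chr(q + 33) for q in phred)
        try:
            yield MergedRead(record.id, str(record.seq).upper(), quality)
        except ValueError as exc:
            raise ValueError(f"{path}: record index {index}: {exc}") from exc
        index += 1


def find_with_mismatches(haystack: str, needle: str, start: int, max_mismatches: int) -> int:
    """Leftmost occurrence of needle in haystack[start:] allowing Hamming
    mismatches; returns the match start or -1.  No indels."""
    if max_mismatches == 0:
        return haystack.find(needle, start)
    n, m = len(haystack), len(needle)
    for pos in range(start, n - m + 1):
        window = haystack[pos : pos + m]
        mismatches = sum(a != b for a, b in zip(window, needle))
        if mismatches <= max_mismatches:
            return pos
    return -1


def trim_flanks(read: MergedRead, flanks: FlankSpec = FlankSpec()) -> Union[CodingRegion, Discard]:
    """Extract the coding region between the two flanks of one read.

    Finds the leftmost 5' flank match, then the first 3' flank match after
    it (each within the Hamming tolerance).  Returns a Discard with reason
    missing-5prime / missing-3prime / empty-insert when no region exists.
    """
    seq = read.sequence
    p5 = find_with_mismatches(seq, flanks.five_prime_fixed, 0, flanks.max_mismatches)
    if p5 < 0:
        return Discard(read.read_id, "missing-5prime")
    insert_start = p5 + len(flanks.five_prime_fixed)
    p3 = find_with_mismatches(seq, flanks.three_prime_fixed, insert_start, flanks.max_mismatches)
    if p3 < 0:
        return Discard(read.read_id, "missing-3prime")
    if p3 == insert_start:
        return Discard(read.read_id, "empty-insert")
    return CodingRegion(read.read_id, seq[insert_start:p3])


def trim_reads(
    reads: Iterable[MergedRead],
    flanks: FlankSpec = FlankSpec(),
    stats: Optional[TrimStats] = None,
) -> Iterator[CodingRegion]:
    """Trim a stream of reads, yielding coding regions and accumulating
    kept/discarded tallies into stats (if given)."""
    for read in reads:
        outcome = trim_flanks(read, flanks)
        if stats is not None:
            stats.total += 1
        if isinstance(outcome, CodingRegion):
            if stats is not None:
                stats.kept += 1
            yield outcome
        elif stats is not None:
            stats.by_reason[outcome.reason] = stats.by_reason.get(outcome.reason, 0) + 1


def write_fasta(records: Iterable, handle_or_path: Union[str, Path, TextIO]) -> int:
    """Write CodingRegion or (id, sequence)-like records as FASTA.

    Returns the number of records written.  Asterisks are permitted in
    sequence lines (translated peptide output).
    """
    own = isinstance(handle_or_path, (str, Path))
    handle = open(handle_or_path, "w") if own else handle_or_path
    n = 0
    try:
        for rec in records:
            if isinstance(rec, CodingRegion):
                rid, seq = rec.read_id, rec.dna
            elif isinstance(rec, tuple):
                rid, seq = rec
            else:  # PeptideRecord-like
                rid, seq = rec.read_id, rec.peptide
            handle.write(f">{rid}\n{seq}\n")
            n += 1
    finally:
        if own:
            handle.close()
    return n
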