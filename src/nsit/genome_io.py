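"""FASTA ingest, normalization, assembly statistics, and scaffold splitting.

All coordinates are 0-based half-open internally; human-readable reports
convert to 1-based inclusive at the formatting layer only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AssemblyStats",
    "read_fasta",
    "write_fasta",
    "compute_stats",
    "split_long_sequences",
    "lift_interval",
    "reverse_complement",
]

# Uppercase, map IUPAC ambiguity codes (and anything else alphabetic that is
# not A/C/G/T) to N.  The k-mer index skips N windows, so this loses nothing.
_NORMALIZE = {}
for _c in range(256):
    ch = chr(_c)
    up = ch.upper()
    if up in "ACGTN":
        _NORMALIZE[_c] = up
    elif up.isalpha():
        _NORMALIZE[_c] = "N"
_NORM_TABLE = str.maketrans(_NORMALIZE)

_VALID_RE = re.compile(r"^[ACGTN]*$")
_N_RUN_RE = re.compile(r"N+")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_seq(seq: str) -> str:
    """Uppercase and collapse the alphabet to {A,C,G,T,N}.

    Raises ``ValueError`` on non-alphabetic characters (digits, gaps, ...).
    """
    out = seq.translate(_NORM_TABLE)
    if not _VALID_RE.match(out):
        bad = sorted({c for c in out if c not in "ACGTN"})
        raise ValueError(f"sequence contains invalid characters: {bad!r}")
    return out


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA string (chromosome, contig, or scaffold).

    ``seq`` is normalized to {A,C,G,T,N}; ``n_runs`` holds the maximal runs
    of N as 0-based half-open ``(start, end)`` intervals, sorted and disjoint.
    """

    id: str
    seq: str
    n_runs: list[tuple[int, int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.seq = normalize_seq(self.seq)
        self.n_runs = [(m.start(), m.end()) for m in _N_RUN_RE.finditer(self.seq)]

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, reverse_complement(self.seq))


@dataclass(frozen=True)
class AssemblyStats:
    n_sequences: int
    total_length: int
    n50: int
    min_length: int
    max_length: int


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving file order.

    Record ids are the first whitespace-delimited token of each header.
    Empty sequences and duplicate ids are hard errors naming the record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


def compute_stats(records: list[SequenceRecord]) -> AssemblyStats:
    """Standard assembly summary; N50 is the length L such that sequences of
    length >= L together contain at least half of the assembly's bases."""
    if not records:
        raise ValueError("cannot compute stats of an empty assembly")
    lengths = sorted((r.length for r in records), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for ln in lengths:
        acc += ln
        if 2 * acc >= total:
            n50 = ln
            break
    return AssemblyStats(
        n_sequences=len(lengths),
        total_length=total,
        n50=n50,
        min_length=lengths[-1],
        max_length=lengths[0],
    )


def piece_id(original_id: str, offset: int) -> str:
    return f"{original_id}__{offset}"


def split_long_sequences(
    records: list[SequenceRecord], target_len: int
) -> tuple[list[SequenceRecord], dict[str, tuple[str, int]]]:
    """Break sequences longer than ``target_len`` into contiguous uniform
    chunks so downstream phases see uniformly sized queries.

    Returns the (possibly split) records plus a mapping from piece id to
    ``(original_id, offset)`` so coordinates can be lifted back.  Sequences
    already within the target are passed through unchanged and do not appear
    in the mapping.
    """
    if target_len < 1:
        raise ValueError("target_len must be >= 1")
    out: list[SequenceRecord] = []
    mapping: dict[str, tuple[str, int]] = {}
    for rec in records:
        if rec.length <= target_len:
            out.append(rec)
            continue
        for off in range(0, rec.length, target_len):
            pid = piece_id(rec.id, off)
            out.append(SequenceRecord(pid, rec.seq[off : off + target_len]))
            mapping[pid] = (rec.id, off)
    return out, mapping


def lift_interval(
    mapping: dict[str, tuple[str, int]], pid: str, start: int, end: int
) -> tuple[str, int, int]:
    """Map a piece-local interval back to original-sequence coordinates."""
    if pid not in mapping:
        return pid, start, end
    orig, off = mapping[pid]
    return orig, start + off, end + off


def write_stats_tsv(stats: AssemblyStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("n_sequences\ttotal_length\tn50\tmin_length\tmax_length\n")
        fh.write(
            f"{stats.n_sequences}\t{stats.total_length}\t{stats.n50}\t"
            f"{stats.min_length}\t{stats.max_length}\n"
        )
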