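"""Seeded generator of reference genomes and derived assemblies with ground
truth, so every pipeline stage is testable without external downloads.

The generator emulates the failure modes real assemblies exhibit: SNPs and
small indels, N gaps from unresolved repeats, chimeric scaffolds fusing two
chromosomes, contigs from a contaminating organism, multi-copy repeat
families in the reference, and implanted novel insertions guaranteed (by
construction) to share no k-mer with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from nsit.genome_io import SequenceRecord, reverse_complement, write_fasta
from nsit.kmer_index import sequence_codes

__all__ = ["SimConfig", "GroundTruth", "TruthPiece", "SimResult", "simulate", "write_fixtures"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_lengths: list[int] = field(default_factory=lambda: [100_000] * 4)
    n_contigs: int = 50
    contig_length_dist: tuple[int, int] = (2_000, 8_000)
    snp_rate: float = 0.0
    indel_rate: float = 0.0
    max_indel_len: int = 5
    novel_insertion_count: int = 0
    novel_length_dist: tuple[int, int] = (100, 2_000)
    novel_kmer: int = 12  # insertions share no k-mer of this size with the reference
    repeat_family_count: int = 0
    repeat_copy_number: int = 3
    repeat_length: int = 400
    n_gap_rate: float = 0.0
    n_gap_length: tuple[int, int] = (10, 100)
    chimera_rate: float = 0.0
    contaminant_fraction: float = 0.0
    contaminant_genome_length: int = 50_000

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "n_gap_rate", "chimera_rate", "contaminant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if len(self.chrom_lengths) != self.n_chroms:
            raise ValueError("chrom_lengths must have n_chroms entries")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.novel_insertion_count and self.novel_length_dist[1] >= self.contig_length_dist[0]:
            raise ValueError(
                "largest novel insertion must be shorter than the smallest contig"
            )


@dataclass(frozen=True)
class TruthPiece:
    """Provenance of one contiguous slice of an emitted contig."""

    start: int  # contig coordinates, half-open
    end: int
    kind: str  # "ref" | "novel" | "contaminant"
    chrom: str | None = None
    ref_start: int | None = None  # source interval before mutation (length may
    ref_end: int | None = None  # differ from end-start when indels applied)
    orientation: str | None = None


@dataclass
class GroundTruth:
    """Per-contig provenance plus the implanted novel intervals."""

    pieces: dict[str, list[TruthPiece]] = field(default_factory=dict)
    novel_intervals: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SimResult:
    reference: list[SequenceRecord]
    assembly: list[SequenceRecord]
    truth: GroundTruth
    contaminant_genome: str = ""


def _mutate(
    seq: str,
    rng: np.random.Generator,
    snp_rate: float,
    indel_rate: float,
    max_indel_len: int,
) -> str:
    """Apply substitutions vectorized, then indels sparsely."""
    digits = np.searchsorted(_BASES, np.frombuffer(seq.encode("ascii"), dtype=np.uint8))
    if snp_rate > 0:
        mask = rng.random(len(digits)) < snp_rate
        n = int(mask.sum())
        if n:
            digits[mask] = (digits[mask] + rng.integers(1, 4, size=n)) % 4
    seq = bytes(_BASES[digits]).decode("ascii")
    if indel_rate > 0:
        events = np.flatnonzero(rng.random(len(seq)) < indel_rate)
        parts = []
        cur = 0
        for pos in events:
            if pos < cur:
                continue
            parts.append(seq[cur:pos])
            size = int(rng.integers(1, max_indel_len + 1))
            if rng.random() < 0.5:  # deletion
                cur = min(len(seq), pos + size)
            else:  # insertion
                parts.append(_random_seq(rng, size))
                cur = pos
        parts.append(seq[cur:])
        seq = "".join(parts)
    return seq


def _novel_sequence(rng: np.random.Generator, length: int, ref_codes: set[int], k: int) -> str:
    """Random sequence none of whose k-mers occur in the reference, built
    base by base with rare backtracking when all four extensions collide."""
    mask = (1 << (2 * k)) - 1
    digits: list[int] = []
    code = 0
    guard = 0
    while len(digits) < length:
        guard += 1
        if guard > 50 * length:
            raise RuntimeError("novel sequence construction failed to converge")
        placed = False
        for b in rng.permutation(4):
            if len(digits) < k - 1:
                digits.append(int(b))
                code = ((code << 2) | int(b)) & mask
                placed = True
                break
            cand = ((code << 2) | int(b)) & mask
            if cand not in ref_codes:
                digits.append(int(b))
                code = cand
                placed = True
                break
        if not placed:
            drop = int(rng.integers(1, min(5, len(digits)) + 1))
            digits = digits[:-drop]
            code = 0
            for d in digits[-(k - 1):]:
                code = ((code << 2) | d) & mask
    return bytes(_BASES[np.array(digits, dtype=np.int64)]).decode("ascii")


def _insert_piece(
    pieces: list[TruthPiece], pos: int, length: int, kind: str
) -> list[TruthPiece]:
    """Split the piece list at ``pos`` and wedge in a new piece, shifting
    everything to the right."""
    out: list[TruthPiece] = []
    for p in pieces:
        if p.end <= pos:
            out.append(p)
        elif p.start >= pos:
            out.append(TruthPiece(p.start + length, p.end + length, p.kind, p.chrom,
                                  p.ref_start, p.ref_end, p.orientation))
        else:  # split
            out.append(TruthPiece(p.start, pos, p.kind, p.chrom,
                                  p.ref_start, p.ref_end, p.orientation))
            out.append(TruthPiece(pos + length, p.end + length, p.kind, p.chrom,
                                  p.ref_start, p.ref_end, p.orientation))
    out.append(TruthPiece(pos, pos + length, kind))
    out.sort(key=lambda p: p.start)
    return out


def simulate(config: SimConfig) -> SimResult:
    """Generate (reference, assembly, ground truth); byte-identical for the
    same config and seed."""
    rng = np.random.default_rng(config.seed)

    # reference chromosomes, optionally seeded with multi-copy repeat motifs
    chrom_seqs = [_random_seq(rng, L) for L in config.chrom_lengths]
    for _ in range(config.repeat_family_count):
        motif = _random_seq(rng, config.repeat_length)
        for _copy in range(config.repeat_copy_number):
            ci = int(rng.integers(0, config.n_chroms))
            if config.chrom_lengths[ci] <= config.repeat_length:
                continue
            pos = int(rng.integers(0, config.chrom_lengths[ci] - config.repeat_length))
            s = chrom_seqs[ci]
            chrom_seqs[ci] = s[:pos] + motif + s[pos + config.repeat_length:]
    reference = [
        SequenceRecord(f"chr{i + 1:02d}", s) for i, s in enumerate(chrom_seqs)
    ]

    contaminant = (
        _random_seq(rng, config.contaminant_genome_length)
        if config.contaminant_fraction > 0
        else ""
    )

    truth = GroundTruth()
    assembly: list[SequenceRecord] = []
    lo, hi = config.contig_length_dist
    for idx in range(config.n_contigs):
        cid = f"ctg{idx + 1:05d}"
        length = int(rng.integers(lo, hi + 1))
        if contaminant and rng.random() < config.contaminant_fraction:
            length = min(length, len(contaminant))
            start = int(rng.integers(0, len(contaminant) - length + 1))
            seq = contaminant[start : start + length]
            pieces = [TruthPiece(0, len(seq), "contaminant")]
        else:
            segments = []
            if config.chimera_rate > 0 and rng.random() < config.chimera_rate and config.n_chroms > 1:
                cut = int(length * (0.4 + 0.2 * rng.random()))
                segments = [cut, length - cut]
            else:
                segments = [length]
            seq_parts: list[str] = []
            pieces = []
            cpos = 0
            prev_chrom = -1
            for seg_len in segments:
                ci = int(rng.integers(0, config.n_chroms))
                if ci == prev_chrom and config.n_chroms > 1:
                    ci = (ci + 1) % config.n_chroms
                prev_chrom = ci
                seg_len = min(seg_len, config.chrom_lengths[ci])
                rstart = int(rng.integers(0, config.chrom_lengths[ci] - seg_len + 1))
                raw = chrom_seqs[ci][rstart : rstart + seg_len]
                orient = "+" if rng.random() < 0.5 else "-"
                if orient == "-":
                    raw = reverse_complement(raw)
                mut = _mutate(raw, rng, config.snp_rate, config.indel_rate, config.max_indel_len)
                if config.n_gap_rate > 0 and rng.random() < config.n_gap_rate and len(mut) > 200:
                    glen = int(rng.integers(config.n_gap_length[0], config.n_gap_length[1] + 1))
                    gpos = int(rng.integers(50, len(mut) - 50))
                    mut = mut[:gpos] + "N" * glen + mut[gpos:]
                seq_parts.append(mut)
                pieces.append(
                    TruthPiece(cpos, cpos + len(mut), "ref",
                               reference[ci].id, rstart, rstart + seg_len, orient)
                )
                cpos += len(mut)
            seq = "".join(seq_parts)
        assembly.append(SequenceRecord(cid, seq))
        truth.pieces[cid] = pieces

    # implant novel insertions into host contigs verified k-mer-absent
    if config.novel_insertion_count:
        k = config.novel_kmer
        ref_codes: set[int] = set()
        for chrom in reference:
            codes = sequence_codes(chrom.seq, k)
            ref_codes.update(int(c) for c in codes[codes >= 0])
        hosts = [
            i for i, rec in enumerate(assembly)
            if truth.pieces[rec.id][0].kind != "contaminant"
        ]
        if not hosts:
            raise ValueError("no non-contaminant contigs available to host insertions")
        nlo, nhi = config.novel_length_dist
        for _ in range(config.novel_insertion_count):
            hi_idx = hosts[int(rng.integers(0, len(hosts)))]
            rec = assembly[hi_idx]
            ins_len = int(rng.integers(nlo, nhi + 1))
            if ins_len >= rec.length:
                raise ValueError(
                    f"insertion of {ins_len} bp does not fit contig {rec.id} ({rec.length} bp)"
                )
            pos = int(rng.integers(1, rec.length - 1))
            ins = _novel_sequence(rng, ins_len, ref_codes, k)
            assembly[hi_idx] = SequenceRecord(rec.id, rec.seq[:pos] + ins + rec.seq[pos:])
            truth.pieces[rec.id] = _insert_piece(truth.pieces[rec.id], pos, ins_len, "novel")
            # shift previously recorded novel intervals on the same contig
            truth.novel_intervals = [
                (cid, s + ins_len, e + ins_len) if cid == rec.id and s >= pos else (cid, s, e)
                for cid, s, e in truth.novel_intervals
            ]
            truth.novel_intervals.append((rec.id, pos, pos + ins_len))

    return SimResult(reference, assembly, truth, contaminant)


def write_fixtures(result: SimResult, out_dir: str | Path) -> None:
    """Persist a simulation as FASTA plus plain-text truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.reference, out / "reference.fa")
    write_fasta(result.assembly, out / "assembly.fa")
    with open(out / "truth_pieces.tsv", "w") as fh:
        fh.write("contig\tstart\tend\tkind\tchrom\tref_start\tref_end\torientation\n")
        for cid in sorted(result.truth.pieces):
            for p in result.truth.pieces[cid]:
                fh.write(
                    f"{cid}\t{p.start}\t{p.end}\t{p.kind}\t{p.chrom or '-'}\t"
                    f"{'-' if p.ref_start is None else p.ref_start}\t"
                    f"{'-' if p.ref_end is None else p.ref_end}\t{p.orientation or '-'}\n"
                )
    with open(out / "novel_truth.bed", "w") as fh:
        for cid, s, e in sorted(result.truth.novel_intervals):
            fh.write(f"{cid}\t{s}\t{e}\n")
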