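"""Per-chromosome k-mer position index with gapped-seed subset filtering.

Each chromosome gets one hash table mapping every N-free k-mer window,
encoded as a base-4 integer, to the ascending list of its 0-based start
positions.  Tables are built and persisted one chromosome at a time; for
the assignment phase they are loaded through a subset filter that keeps
only seed positions on a fixed stride, which realizes the gapped
(non-consecutive) seeding scheme.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from nsit.genome_io import SequenceRecord, read_fasta

__all__ = [
    "SENTINEL",
    "encode_kmer",
    "decode_kmer",
    "sequence_codes",
    "KmerIndex",
    "SeedConfig",
    "build_index",
    "filter_index",
    "seed_positions",
    "save_index",
    "load_index",
    "MemoryIndexStore",
    "DirIndexStore",
]

SENTINEL = -1

_BASE_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_DIGIT_BASE = "ACGT"

# byte -> base-4 digit; N (and only N) maps to a negative marker
_DIGIT_LUT = np.full(256, -(10 ** 6), dtype=np.int64)
for _b, _d in _BASE_DIGIT.items():
    _DIGIT_LUT[ord(_b)] = _d
_DIGIT_LUT[ord("N")] = -(10 ** 6)

_MAGIC = b"NSIDX1\n"
_VERSION = 1


def encode_kmer(kmer: str) -> int:
    """Base-4 positional code of a k-mer: A=0, C=1, G=2, T=3, the leftmost
    base being the most significant digit.  Returns ``SENTINEL`` if the
    k-mer contains N; any other character is an error."""
    code = 0
    for ch in kmer:
        if ch == "N":
            return SENTINEL
        try:
            code = (code << 2) | _BASE_DIGIT[ch]
        except KeyError:
            raise ValueError(f"invalid base {ch!r} in k-mer") from None
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append(_DIGIT_BASE[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def sequence_codes(seq: str, k: int) -> np.ndarray:
    """Codes of all length-k windows of ``seq`` (length L-k+1); windows that
    contain an N get ``SENTINEL``.  Vectorized: k shifted adds."""
    L = len(seq)
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    digits = _DIGIT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes += digits[j : j + n] << (2 * (k - 1 - j))
    codes[codes < 0] = SENTINEL
    return codes


@dataclass
class KmerIndex:
    """Map from k-mer code to the ascending array of occurrence positions."""

    chrom_id: str
    k: int
    table: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.table.values())

    def positions(self, code: int) -> np.ndarray | None:
        if code == SENTINEL:
            return None
        return self.table.get(code)


@dataclass
class SeedConfig:
    """Gapped-seed geometry for the assignment phase.

    Consecutive seeds within one set are ``k + gap`` bases apart; the
    ``n_sets`` sets are staggered by ``delta = (k + gap) / n_sets`` bases,
    which must divide evenly.  ``min_mum_len`` is the minimum span of a
    maximal unique aligned region; ``prune_dist`` is the anchor-pruning
    radius on the reference.
    """

    k: int = 12
    gap: int = 84
    n_sets: int = 6
    min_mum_len: int = 200
    prune_dist: int = 1_000_000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.n_sets < 1:
            raise ValueError("n_sets must be positive")
        if (self.k + self.gap) % self.n_sets != 0:
            raise ValueError(
                f"(k + gap) = {self.k + self.gap} is not divisible by n_sets = {self.n_sets}"
            )
        if not 8 <= self.k <= 16:
            warnings.warn(f"k={self.k} is outside the recommended 8-16 range", stacklevel=2)
        if self.n_sets > 1 and not 10 <= self.delta <= 20:
            warnings.warn(
                f"inter-set offset delta={self.delta} is outside the recommended 10-20 range",
                stacklevel=2,
            )
        if self.min_mum_len <= 25:
            warnings.warn(
                "min_mum_len <= 25 admits non-unique matches; most 25-mers are "
                "genome-unique so a larger threshold is recommended",
                stacklevel=2,
            )
        # Advisory: a minimum-length region should contain >= 3 seeds.
        if self.min_mum_len < 2 * (self.k + self.gap) + self.k:
            warnings.warn(
                f"min_mum_len={self.min_mum_len} allows regions with fewer than 3 "
                f"seed matches at period {self.k + self.gap}",
                stacklevel=2,
            )

    @property
    def period(self) -> int:
        """Distance between consecutive seeds within one set."""
        return self.k + self.gap

    @property
    def delta(self) -> int:
        """Offset between the first seeds of consecutive sets."""
        return self.period // self.n_sets

    @property
    def is_full_density(self) -> bool:
        """gap=0 with a single set degenerates to using every position."""
        return self.gap == 0 and self.n_sets == 1


def seed_positions(config: SeedConfig):
    """Predicate selecting the reference positions kept for gapped seeding.

    A position is retained iff it is a multiple of ``delta``; the retained
    positions decompose into exactly ``n_sets`` residue classes mod
    ``period``, class j starting at ``j * delta``.  The degenerate gap-free
    single-set configuration retains every position.
    """
    if config.is_full_density:
        return lambda p: True
    delta = config.delta
    return lambda p: p % delta == 0


def build_index(chrom: SequenceRecord, k: int) -> KmerIndex:
    """Index every N-free k-mer window of a chromosome.

    A chromosome shorter than k yields an empty index with a warning.
    """
    if chrom.length < k:
        warnings.warn(f"chromosome {chrom.id!r} is shorter than k={k}; empty index")
        return KmerIndex(chrom.id, k)
    codes = sequence_codes(chrom.seq, k)
    valid = np.flatnonzero(codes != SENTINEL)
    if len(valid) == 0:
        return KmerIndex(chrom.id, k)
    vcodes = codes[valid]
    order = np.argsort(vcodes, kind="stable")  # stable keeps positions ascending
    sorted_codes = vcodes[order]
    sorted_pos = valid[order].astype(np.int64)
    uniq, starts = np.unique(sorted_codes, return_index=True)
    bounds = np.append(starts, len(sorted_codes))
    table = {
        int(uniq[i]): sorted_pos[bounds[i] : bounds[i + 1]] for i in range(len(uniq))
    }
    return KmerIndex(chrom.id, k, table)


def filter_index(index: KmerIndex, config: SeedConfig) -> KmerIndex:
    """Materialize only the seed-subset positions (multiples of delta)."""
    if config.is_full_density:
        return index
    delta = config.delta
    table: dict[int, np.ndarray] = {}
    for code, pos in index.table.items():
        kept = pos[pos % delta == 0]
        if len(kept):
            table[code] = kept
    return KmerIndex(index.chrom_id, index.k, table)


def save_index(index: KmerIndex, path: str | Path) -> None:
    """Small binary format: magic, version, k, chrom id, then the code /
    count / position arrays.  One file per chromosome."""
    codes = np.fromiter(sorted(index.table), dtype=np.int64, count=len(index.table))
    counts = np.fromiter(
        (len(index.table[int(c)]) for c in codes), dtype=np.int64, count=len(codes)
    )
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        ident = index.chrom_id.encode("utf-8")
        fh.write(struct.pack("<IIQ", _VERSION, index.k, len(ident)))
        fh.write(ident)
        fh.write(struct.pack("<Q", len(codes)))
        codes.tofile(fh)
        counts.tofile(fh)
        for c in codes:
            index.table[int(c)].astype(np.int64).tofile(fh)


def load_index(path: str | Path, subset_filter: SeedConfig | None = None) -> KmerIndex:
    """Load a persisted index; with ``subset_filter`` only seed-subset
    positions are materialized.  save -> load (no filter) is the identity."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not an index file (bad magic)")
        version, k, id_len = struct.unpack("<IIQ", fh.read(16))
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported index version {version}")
        chrom_id = fh.read(id_len).decode("utf-8")
        if subset_filter is not None and subset_filter.k != k:
            raise ValueError(
                f"{path}: index built with k={k} but seed config has k={subset_filter.k}"
            )
        (n_codes,) = struct.unpack("<Q", fh.read(8))
        codes = np.fromfile(fh, dtype=np.int64, count=n_codes)
        counts = np.fromfile(fh, dtype=np.int64, count=n_codes)
        total = int(counts.sum())
        flat = np.fromfile(fh, dtype=np.int64, count=total)
        if len(flat) != total:
            raise ValueError(f"{path}: truncated index file")
    table: dict[int, np.ndarray] = {}
    delta = None
    if subset_filter is not None and not subset_filter.is_full_density:
        delta = subset_filter.delta
    off = 0
    for code, cnt in zip(codes, counts):
        pos = flat[off : off + cnt]
        off += cnt
        if delta is not None:
            pos = pos[pos % delta == 0]
            if len(pos) == 0:
                continue
        table[int(code)] = pos
    return KmerIndex(chrom_id, int(k), table)


class MemoryIndexStore:
    """Index provider that builds per-chromosome tables on demand from
    in-memory reference records (one table alive at a time)."""

    def __init__(self, reference: list[SequenceRecord], k: int):
        self._by_id = {r.id: r for r in reference}
        self.chrom_ids = [r.id for r in reference]
        self.k = k

    def load(self, chrom_id: str, subset_filter: SeedConfig | None = None) -> KmerIndex:
        idx = build_index(self._by_id[chrom_id], self.k)
        if subset_filter is not None:
            idx = filter_index(idx, subset_filter)
        return idx


class DirIndexStore:
    """Index provider over a directory of persisted per-chromosome files
    written by :func:`write_index_dir`."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        manifest = self.path / "index.tsv"
        if not manifest.exists():
            raise FileNotFoundError(f"no index manifest at {manifest}")
        self.chrom_ids: list[str] = []
        self._files: dict[str, Path] = {}
        with open(manifest) as fh:
            header = fh.readline()
            for line in fh:
                chrom_id, fname, k = line.rstrip("\n").split("\t")
                self.chrom_ids.append(chrom_id)
                self._files[chrom_id] = self.path / fname
                self.k = int(k)

    def load(self, chrom_id: str, subset_filter: SeedConfig | None = None) -> KmerIndex:
        return load_index(self._files[chrom_id], subset_filter)


def write_index_dir(reference: list[SequenceRecord], k: int, out_dir: str | Path) -> None:
    """Index a reference one chromosome at a time into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, chrom in enumerate(reference):
        fname = f"chrom{i:03d}.nsidx"
        save_index(build_index(chrom, k), out / fname)
        rows.append((chrom.id, fname, k))
    with open(out / "index.tsv", "w") as fh:
        fh.write("chrom_id\tfile\tk\n")
        for chrom_id, fname, kk in rows:
            fh.write(f"{chrom_id}\t{fname}\t{kk}\n")


def index_reference_file(ref_path: str | Path, k: int, out_dir: str | Path) -> None:
    write_index_dir(read_fasta(ref_path), k, out_dir)
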