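"""Phase 2: candidate chromosome/orientation assignment via gapped seeds.

Each query is scanned left to right in both orientations against every
chromosome's seed-filtered index.  Stretches of k-mer matches that chain to
a unique reference location (maximal unique aligned regions) are collected,
pruned around the longest region, and summed into one score per
(chromosome, orientation) slot — 48 slots for a 24-chromosome reference.
A slot is assigned when its score is a Gaussian outlier among all slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nsit.genome_io import SequenceRecord, reverse_complement
from nsit.kmer_index import KmerIndex, SeedConfig, SENTINEL, sequence_codes

__all__ = [
    "AlignedRegion",
    "ScoreMatrix",
    "gapped_scan",
    "prune_spurious",
    "score_regions",
    "assign_targets",
    "assign_queries",
    "Z_CRIT_DEFAULT",
]

#: one-sided standard-normal quantile for p = 0.01
Z_CRIT_DEFAULT = 2.326

FORWARD = "+"
REVERSE = "-"
ORIENTATIONS = (FORWARD, REVERSE)


@dataclass(frozen=True)
class AlignedRegion:
    """One maximal unique stretch of chained k-mer matches.

    Query coordinates are in the scanned orientation of the query (i.e. in
    reverse-complement coordinates when ``orientation == '-'``); reference
    coordinates are always forward.  Regions are gap-free, so the query and
    reference spans are equal.
    """

    chrom_id: str
    orientation: str
    q_start: int
    q_end: int
    r_start: int
    r_end: int
    n_seeds: int

    @property
    def span(self) -> int:
        return self.q_end - self.q_start

    def shifted(self, q_shift: int, r_shift: int = 0) -> "AlignedRegion":
        return AlignedRegion(
            self.chrom_id,
            self.orientation,
            self.q_start + q_shift,
            self.q_end + q_shift,
            self.r_start + r_shift,
            self.r_end + r_shift,
            self.n_seeds,
        )


def chain_scan(
    query_codes: np.ndarray,
    index: KmerIndex,
    orientation: str,
    step: int,
    min_len: int,
    stats: dict | None = None,
) -> list[AlignedRegion]:
    """Greedy left-to-right seed chaining against one chromosome table.

    At each query position the seed's reference position list is looked up;
    a candidate region grows by intersecting the current set of possible
    region starts with the next seed's positions shifted back by
    ``t * step``.  The region ends when no further seed continues it; it is
    emitted only if the surviving set is unique and the span reaches
    ``min_len``.  Scanning then restarts at the base following the chain,
    so each query base triggers at most one seed lookup per orientation.
    """
    k = index.k
    table = index.table
    n = len(query_codes)
    regions: list[AlignedRegion] = []
    lookups = 0
    q = 0
    while q < n:
        code = int(query_codes[q])
        lookups += 1
        plist = table.get(code) if code != SENTINEL else None
        if plist is None:
            q += 1
            continue
        starts: set[int] = set(int(p) for p in plist)
        t = 1
        while True:
            nq = q + t * step
            if nq >= n:
                break
            code2 = int(query_codes[nq])
            lookups += 1
            plist2 = table.get(code2) if code2 != SENTINEL else None
            if plist2 is None:
                break
            shift = t * step
            nxt = starts.intersection(int(p) - shift for p in plist2)
            if not nxt:
                break
            starts = nxt
            t += 1
        span = (t - 1) * step + k
        if len(starts) == 1 and span >= min_len:
            r0 = next(iter(starts))
            regions.append(
                AlignedRegion(index.chrom_id, orientation, q, q + span, r0, r0 + span, t)
            )
        q += span
    if stats is not None:
        stats["lookups"] = stats.get("lookups", 0) + lookups
    return regions


def gapped_scan(
    query: SequenceRecord,
    index: KmerIndex,
    orientation: str,
    config: SeedConfig,
    stats: dict | None = None,
) -> list[AlignedRegion]:
    """Scan one orientation of a query against a seed-filtered index.

    For the reverse orientation the query itself is reverse-complemented;
    the reference index is never reversed.
    """
    seq = query.seq if orientation == FORWARD else reverse_complement(query.seq)
    codes = sequence_codes(seq, config.k)
    return chain_scan(codes, index, orientation, config.period, config.min_mum_len, stats)


def prune_spurious(regions: list[AlignedRegion], prune_dist: int) -> list[AlignedRegion]:
    """Keep only regions near the anchor (the longest region; ties broken by
    smallest reference start).  Distance is measured between reference start
    coordinates.  The anchor itself is always retained."""
    if not regions:
        return []
    anchor = max(regions, key=lambda r: (r.span, -r.r_start))
    return [r for r in regions if abs(r.r_start - anchor.r_start) <= prune_dist]


def score_regions(regions: list[AlignedRegion]) -> int:
    """Alignment score = total number of bases in the retained regions."""
    return sum(r.span for r in regions)


@dataclass
class ScoreMatrix:
    """Per-query alignment scores over all (chromosome, orientation) slots."""

    query_id: str
    chrom_ids: list[str]
    scores: np.ndarray  # shape (n_chroms, 2); columns: forward, reverse
    mu: float = 0.0
    sigma: float = 0.0
    assigned: set[tuple[str, str]] = field(default_factory=set)

    @classmethod
    def empty(cls, query_id: str, chrom_ids: list[str]) -> "ScoreMatrix":
        return cls(query_id, list(chrom_ids), np.zeros((len(chrom_ids), 2), dtype=np.int64))

    @property
    def n_slots(self) -> int:
        return self.scores.size

    def set_score(self, chrom_id: str, orientation: str, score: int) -> None:
        i = self.chrom_ids.index(chrom_id)
        self.scores[i, 0 if orientation == FORWARD else 1] = score

    def score(self, chrom_id: str, orientation: str) -> int:
        i = self.chrom_ids.index(chrom_id)
        return int(self.scores[i, 0 if orientation == FORWARD else 1])

    def zscore(self, chrom_id: str, orientation: str) -> float:
        if self.sigma == 0:
            return 0.0
        return (self.score(chrom_id, orientation) - self.mu) / self.sigma


def assign_targets(
    matrix: ScoreMatrix,
    z_crit: float = Z_CRIT_DEFAULT,
    leave_one_out: bool = False,
) -> set[tuple[str, str]]:
    """Flag slots whose score is a one-sided Gaussian outlier.

    Chance-match scores are modeled as Gaussian noise over the slots; a slot
    is assigned iff (score - mu) / sigma >= z_crit with sigma > 0 (population
    standard deviation over all slots).  With ``leave_one_out`` mu and sigma
    for each slot are computed from the other slots only.
    """
    flat = matrix.scores.astype(float).ravel()
    mu = float(flat.mean())
    sigma = float(flat.std())
    matrix.mu = mu
    matrix.sigma = sigma
    assigned: set[tuple[str, str]] = set()
    for i, chrom_id in enumerate(matrix.chrom_ids):
        for j, orient in enumerate(ORIENTATIONS):
            s = float(matrix.scores[i, j])
            if leave_one_out:
                others = np.delete(flat, i * 2 + j)
                m = float(others.mean())
                sd = float(others.std())
            else:
                m, sd = mu, sigma
            if sd > 0 and (s - m) / sd >= z_crit:
                assigned.add((chrom_id, orient))
    matrix.assigned = assigned
    return assigned


def assign_queries(
    index_store,
    queries: list[SequenceRecord],
    config: SeedConfig,
    z_crit: float = Z_CRIT_DEFAULT,
    leave_one_out: bool = False,
    stats: dict | None = None,
) -> dict[str, ScoreMatrix]:
    """Run the assignment phase for all queries.

    Chromosome indexes are loaded (seed-filtered) one at a time, so memory
    is bounded by the largest single chromosome table.  Queries shorter than
    ``min_mum_len`` are routed straight to the unassigned group without
    scanning.
    """
    chrom_ids = index_store.chrom_ids
    matrices = {q.id: ScoreMatrix.empty(q.id, chrom_ids) for q in queries}
    scannable = [q for q in queries if q.length >= config.min_mum_len]
    # query seed codes are orientation-specific but chromosome-independent
    codes: dict[str, dict[str, np.ndarray]] = {}
    for q in scannable:
        codes[q.id] = {
            FORWARD: sequence_codes(q.seq, config.k),
            REVERSE: sequence_codes(reverse_complement(q.seq), config.k),
        }
    for chrom_id in chrom_ids:
        index = index_store.load(chrom_id, subset_filter=config)
        for q in scannable:
            for orient in ORIENTATIONS:
                regions = chain_scan(
                    codes[q.id][orient], index, orient, config.period,
                    config.min_mum_len, stats,
                )
                kept = prune_spurious(regions, config.prune_dist)
                matrices[q.id].set_score(chrom_id, orient, score_regions(kept))
    for q in queries:
        assign_targets(matrices[q.id], z_crit=z_crit, leave_one_out=leave_one_out)
    return matrices


def write_assignments_tsv(matrices: dict[str, ScoreMatrix], queries, path) -> None:
    """TSV report: query, length, assigned slots, best score, best z."""
    lengths = {q.id: q.length for q in queries}
    with open(path, "w") as fh:
        fh.write("query_id\tlength\tassigned\tscore\tz\n")
        for qid, m in matrices.items():
            if m.assigned:
                slots = sorted(m.assigned, key=lambda t: (m.chrom_ids.index(t[0]), t[1]))
                lab = ";".join(f"{c}:{o}" for c, o in slots)
                best = max(slots, key=lambda t: m.score(*t))
                score = m.score(*best)
                z = m.zscore(*best)
            else:
                lab, score, z = "-", 0, 0.0
            fh.write(f"{qid}\t{lengths.get(qid, 0)}\t{lab}\t{score}\t{z:.3f}\n")


def read_assignments_tsv(path) -> dict[str, list[tuple[str, str]]]:
    out: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            qid, _len, lab, _s, _z = line.rstrip("\n").split("\t")
            if lab == "-":
                out[qid] = []
            else:
                out[qid] = [tuple(x.rsplit(":", 1)) for x in lab.split(";")]  # type: ignore
    return out
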