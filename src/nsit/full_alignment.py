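"""Phase 3: full-density alignment of the four query groups.

Queries are re-scanned against unfiltered (every indexed k-mer, no
skipping) chromosome tables using the same chaining-by-intersection logic
as the assignment phase.  Blocks are extended by direct base comparison,
overlaps are resolved longest-first with seeded random tie-breaks, and for
each query the highest-scoring target alignment wins.  Large unaligned
runs inside otherwise well-aligned queries are excised and re-aligned
genome-wide before being allowed to become novel-sequence candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nsit._intervals import complement, subtract, total_length
from nsit.assignment import (
    FORWARD,
    ORIENTATIONS,
    REVERSE,
    AlignedRegion,
    chain_scan,
)
from nsit.genome_io import SequenceRecord, reverse_complement
from nsit.kmer_index import KmerIndex, sequence_codes

__all__ = [
    "AlignConfig",
    "FinalAlignment",
    "QueryResult",
    "full_scan",
    "extend_blocks",
    "resolve_overlaps",
    "best_alignment",
    "classify_queries",
    "align_query_to_target",
    "run_query_alignment",
]

GROUP_ASSIGNED = "assigned"
GROUP_UNASSIGNED = "unassigned"
GROUP_MISASSIGNED = "misassigned"
GROUP_FP = "fp_candidate"


@dataclass
class AlignConfig:
    """Knobs for the full-density alignment phase."""

    k: int = 12
    min_block_len: int | None = None  # default 2k: well below min_mum_len, above noise
    fp_cutoff: int = 2500  # unaligned runs larger than this are re-aligned genome-wide

    def __post_init__(self) -> None:
        if self.min_block_len is None:
            self.min_block_len = 2 * self.k


@dataclass
class FinalAlignment:
    """Resolved alignment of one query; block query coordinates are native
    (forward-strand) query coordinates and pairwise non-overlapping."""

    query_id: str
    query_length: int
    blocks: list[AlignedRegion] = field(default_factory=list)

    @property
    def aligned_bases(self) -> int:
        return sum(b.span for b in self.blocks)

    @property
    def coverage_fraction(self) -> float:
        if self.query_length == 0:
            return 0.0
        return self.aligned_bases / self.query_length

    def unaligned_runs(self) -> list[tuple[int, int]]:
        return complement([(b.q_start, b.q_end) for b in self.blocks], self.query_length)


@dataclass
class QueryResult:
    query_id: str
    group: str
    alignment: FinalAlignment
    fp_intervals: list[tuple[int, int]] = field(default_factory=list)


def full_scan(
    query: SequenceRecord,
    index: KmerIndex,
    orientation: str,
    min_block_len: int,
    stats: dict | None = None,
) -> list[AlignedRegion]:
    """Full-density scan: gapped scan degenerated to gap 0 and a single seed
    set, i.e. consecutive k-mers with no skipping."""
    seq = query.seq if orientation == FORWARD else reverse_complement(query.seq)
    codes = sequence_codes(seq, index.k)
    return chain_scan(codes, index, orientation, index.k, min_block_len, stats)


def extend_blocks(
    blocks: list[AlignedRegion], query_seq: str, chrom_seq: str
) -> list[AlignedRegion]:
    """Grow each block base-by-base in both directions while the query and
    reference agree; N never matches.  ``query_seq`` must be in the scanned
    orientation of the blocks."""
    out = []
    for b in blocks:
        qs, qe, rs, re_ = b.q_start, b.q_end, b.r_start, b.r_end
        while qs > 0 and rs > 0 and query_seq[qs - 1] == chrom_seq[rs - 1] != "N":
            qs -= 1
            rs -= 1
        qn, rn = len(query_seq), len(chrom_seq)
        while qe < qn and re_ < rn and query_seq[qe] == chrom_seq[re_] != "N":
            qe += 1
            re_ += 1
        out.append(AlignedRegion(b.chrom_id, b.orientation, qs, qe, rs, re_, b.n_seeds))
    return out


def resolve_overlaps(
    blocks: list[AlignedRegion],
    rng: np.random.Generator,
    min_block_len: int,
) -> list[AlignedRegion]:
    """Longer blocks take priority; overlapped parts of shorter blocks are
    trimmed away (splitting them if needed) and pieces that fall below
    ``min_block_len`` are dropped.  Equal lengths are ordered by a seeded
    random shuffle, so ties depend only on the generator state."""
    if not blocks:
        return []
    tiebreak = rng.permutation(len(blocks))
    order = sorted(range(len(blocks)), key=lambda i: (-blocks[i].span, tiebreak[i]))
    kept: list[tuple[int, int]] = []
    out: list[AlignedRegion] = []
    for i in order:
        b = blocks[i]
        for s, e in subtract([(b.q_start, b.q_end)], kept):
            if e - s < min_block_len:
                continue
            off = s - b.q_start
            out.append(
                AlignedRegion(
                    b.chrom_id, b.orientation, s, e,
                    b.r_start + off, b.r_start + off + (e - s), b.n_seeds,
                )
            )
            kept.append((s, e))
    out.sort(key=lambda r: r.q_start)
    return out


def _to_native(blocks: list[AlignedRegion], query_length: int) -> list[AlignedRegion]:
    """Reflect reverse-orientation block coordinates back onto the forward
    strand of the query."""
    out = []
    for b in blocks:
        if b.orientation == FORWARD:
            out.append(b)
        else:
            out.append(
                AlignedRegion(
                    b.chrom_id, b.orientation,
                    query_length - b.q_end, query_length - b.q_start,
                    b.r_start, b.r_end, b.n_seeds,
                )
            )
    out.sort(key=lambda r: r.q_start)
    return out


def align_query_to_target(
    query: SequenceRecord,
    chrom: SequenceRecord,
    index: KmerIndex,
    orientation: str,
    cfg: AlignConfig,
    rng: np.random.Generator,
    stats: dict | None = None,
) -> FinalAlignment:
    """Scan, extend, and overlap-resolve one query against one
    (chromosome, orientation) target; blocks come back in native query
    coordinates."""
    blocks = full_scan(query, index, orientation, cfg.min_block_len, stats)
    seq = query.seq if orientation == FORWARD else reverse_complement(query.seq)
    blocks = extend_blocks(blocks, seq, chrom.seq)
    blocks = resolve_overlaps(blocks, rng, cfg.min_block_len)
    return FinalAlignment(query.id, query.length, _to_native(blocks, query.length))


def best_alignment(candidates: list[FinalAlignment]) -> FinalAlignment:
    """Highest aligned-base count wins; ties go to the earliest candidate in
    the given order (callers order candidates by chromosome rank with
    forward before reverse, making the winner deterministic)."""
    if not candidates:
        raise ValueError("best_alignment requires at least one candidate")
    return max(candidates, key=lambda a: a.aligned_bases)


def classify_queries(
    alignments: dict[str, FinalAlignment],
    assignments: dict[str, list[tuple[str, str]]],
    fp_cutoff: int,
) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]]]:
    """Label each query and find the large unaligned runs to excise.

    A query with no assigned slot is unassigned; an assigned query whose
    best alignment covers no more than half its length is misassigned.
    Within the remaining (well-aligned) queries, maximal unaligned runs
    strictly longer than ``fp_cutoff`` become false-positive candidate
    subqueries to be re-aligned against all targets.
    """
    labels: dict[str, str] = {}
    fp_runs: dict[str, list[tuple[int, int]]] = {}
    for qid, aln in alignments.items():
        if not assignments.get(qid):
            labels[qid] = GROUP_UNASSIGNED
        elif aln.coverage_fraction <= 0.5:
            labels[qid] = GROUP_MISASSIGNED
        else:
            labels[qid] = GROUP_ASSIGNED
            runs = [iv for iv in aln.unaligned_runs() if iv[1] - iv[0] > fp_cutoff]
            if runs:
                fp_runs[qid] = runs
    return labels, fp_runs


def _align_to_targets(
    queries: list[SequenceRecord],
    targets: dict[str, list[tuple[str, str]]],
    index_store,
    reference_by_id: dict[str, SequenceRecord],
    cfg: AlignConfig,
    rng: np.random.Generator,
    stats: dict | None = None,
) -> dict[str, FinalAlignment]:
    """Align each query to its listed targets, loading one chromosome index
    at a time, and keep the best alignment per query."""
    by_id = {q.id: q for q in queries}
    cand: dict[str, dict[tuple[str, str], FinalAlignment]] = {q.id: {} for q in queries}
    needed: dict[str, list[tuple[str, str]]] = {}
    for qid, tgts in targets.items():
        for chrom_id, orient in tgts:
            needed.setdefault(chrom_id, []).append((qid, orient))
    for chrom_id in index_store.chrom_ids:
        if chrom_id not in needed:
            continue
        index = index_store.load(chrom_id)
        chrom = reference_by_id[chrom_id]
        for qid, orient in needed[chrom_id]:
            cand[qid][(chrom_id, orient)] = align_query_to_target(
                by_id[qid], chrom, index, orient, cfg, rng, stats
            )
    out: dict[str, FinalAlignment] = {}
    for qid, tgts in targets.items():
        ordered = [cand[qid][t] for t in tgts if t in cand[qid]]
        if ordered:
            out[qid] = best_alignment(ordered)
        else:
            out[qid] = FinalAlignment(qid, by_id[qid].length)
    return out


def _all_targets(chrom_ids: list[str]) -> list[tuple[str, str]]:
    return [(c, o) for c in chrom_ids for o in ORIENTATIONS]


def run_query_alignment(
    index_store,
    reference: list[SequenceRecord],
    queries: list[SequenceRecord],
    assignments: dict[str, list[tuple[str, str]]],
    cfg: AlignConfig,
    rng_seed: int = 0,
    stats: dict | None = None,
) -> dict[str, QueryResult]:
    """Run the full query-alignment phase.

    Group 1 (assigned) queries are aligned to their assigned targets only;
    unassigned and misassigned queries are re-aligned against every
    chromosome in both orientations; large unaligned runs excised from the
    first three groups' results are aligned likewise and their blocks merged
    back into the originating query.
    """
    rng = np.random.default_rng(rng_seed)
    reference_by_id = {r.id: r for r in reference}
    chrom_ids = index_store.chrom_ids
    by_id = {q.id: q for q in queries}

    # group 1: assigned queries against their assigned targets
    assigned_targets = {qid: tgts for qid, tgts in assignments.items() if tgts}
    group1 = [by_id[qid] for qid in assigned_targets]
    alignments = _align_to_targets(
        group1, assigned_targets, index_store, reference_by_id, cfg, rng, stats
    )
    for q in queries:
        if q.id not in alignments:
            alignments[q.id] = FinalAlignment(q.id, q.length)

    labels, _ = classify_queries(alignments, assignments, cfg.fp_cutoff)

    # groups 2 and 3: genome-wide re-alignment
    wide_ids = [qid for qid, lab in labels.items() if lab != GROUP_ASSIGNED]
    if wide_ids:
        wide = _align_to_targets(
            [by_id[qid] for qid in wide_ids],
            {qid: _all_targets(chrom_ids) for qid in wide_ids},
            index_store, reference_by_id, cfg, rng, stats,
        )
        alignments.update(wide)

    # group 4: excise large unaligned runs from groups 1-3 results and
    # re-align them genome-wide before they can be called novel
    fp_runs: dict[str, list[tuple[int, int]]] = {}
    for qid, aln in alignments.items():
        if not aln.blocks:
            continue  # wholly unaligned queries were already tried genome-wide
        runs = [iv for iv in aln.unaligned_runs() if iv[1] - iv[0] > cfg.fp_cutoff]
        if runs:
            fp_runs[qid] = runs
    sub_queries: list[SequenceRecord] = []
    sub_origin: dict[str, tuple[str, int]] = {}
    for qid, runs in fp_runs.items():
        for s, e in runs:
            sid = f"{qid}|fp|{s}-{e}"
            sub_queries.append(SequenceRecord(sid, by_id[qid].seq[s:e]))
            sub_origin[sid] = (qid, s)
    if sub_queries:
        sub_aln = _align_to_targets(
            sub_queries,
            {sq.id: _all_targets(chrom_ids) for sq in sub_queries},
            index_store, reference_by_id, cfg, rng, stats,
        )
        for sid, aln in sub_aln.items():
            qid, off = sub_origin[sid]
            alignments[qid].blocks.extend(b.shifted(off) for b in aln.blocks)
            alignments[qid].blocks.sort(key=lambda b: b.q_start)

    return {
        qid: QueryResult(qid, labels[qid], alignments[qid], fp_runs.get(qid, []))
        for qid in alignments
    }


def tally_results(results: dict[str, QueryResult]) -> dict[str, int]:
    """Per-phase base bookkeeping for the run log."""
    tally = {
        "bases_assigned": 0,
        "bases_unassigned": 0,
        "bases_misassigned": 0,
        "bases_fp_candidate": 0,
        "bases_aligned": 0,
        "bases_unaligned": 0,
    }
    for res in results.values():
        L = res.alignment.query_length
        tally[f"bases_{res.group}"] += L
        tally["bases_fp_candidate"] += total_length(res.fp_intervals)
        tally["bases_aligned"] += res.alignment.aligned_bases
        tally["bases_unaligned"] += L - res.alignment.aligned_bases
    return tally


def write_blocks_tsv(results: dict[str, QueryResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tq_start\tq_end\tchrom\tr_start\tr_end\torient\tgroup\n")
        for qid in sorted(results):
            res = results[qid]
            for b in res.alignment.blocks:
                fh.write(
                    f"{qid}\t{b.q_start}\t{b.q_end}\t{b.chrom_id}\t"
                    f"{b.r_start}\t{b.r_end}\t{b.orientation}\t{res.group}\n"
                )


def write_unaligned_bed(results: dict[str, QueryResult], path) -> None:
    with open(path, "w") as fh:
        for qid in sorted(results):
            for s, e in results[qid].alignment.unaligned_runs():
                fh.write(f"{qid}\t{s}\t{e}\n")
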