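"""Novel-sequence candidate extraction and post-filtering.

The unaligned remainder of each query becomes a candidate; candidates are
then whittled down by external evidence parsed from BLAST tabular output
(homology to the reference at high identity, contaminant screens) and
RepeatMasker .out files (known repeats).  This module only parses those
tools' outputs — running them is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from nsit._intervals import intersect, subtract, total_length
from nsit.full_alignment import QueryResult
from nsit.genome_io import SequenceRecord

__all__ = [
    "NovelCandidate",
    "Mask",
    "BlastHit",
    "extract_candidates",
    "parse_blast_tab",
    "parse_repeatmasker_out",
    "blast_masks",
    "repeat_masks",
    "subtract_and_refilter",
    "contamination_screen",
    "FilterReport",
    "base_accounting",
]

MIN_NOVEL_LEN_DEFAULT = 100
IDENTITY_CEILING_DEFAULT = 90.0


@dataclass(frozen=True)
class NovelCandidate:
    """An unaligned query subinterval surviving the filters so far.

    ``start``/``end`` are current query-local coordinates.  ``source_name``
    and ``source_start`` identify the originally extracted candidate this
    piece descends from: external masks (BLAST/RepeatMasker runs on the
    extracted candidate FASTA) are keyed by that name and expressed in
    coordinates local to ``source_start``, so they keep applying after
    earlier filters have trimmed or split the candidate.

    ``anchor`` is the nearest flanking aligned block as
    (chrom, reference position, "left"|"right"), or None for wholly
    unaligned ("unplaced") queries.  ``filter_trail`` records
    (filter name, bases removed) events, newest last.
    """

    query_id: str
    start: int
    end: int
    origin_length: int
    anchor: tuple[str, int, str] | None = None
    filter_trail: tuple[tuple[str, int], ...] = ()
    source_name: str = ""
    source_start: int = -1

    def __post_init__(self) -> None:
        if self.source_start < 0:
            object.__setattr__(self, "source_start", self.start)
        if not self.source_name:
            object.__setattr__(self, "source_name", self.name)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        """Id of this piece (FASTA header key at extraction time)."""
        return f"{self.query_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    q_start: int  # 0-based half-open on the query
    q_end: int
    subject_id: str
    identity: float
    evalue: float


@dataclass(frozen=True)
class Mask:
    """A maskable interval on an extracted candidate, in coordinates local
    to that candidate's sequence (keyed by candidate name)."""

    candidate_id: str
    start: int
    end: int
    source: str = ""
    identity: float | None = None


def _nearest_anchor(aln, s: int, e: int) -> tuple[str, int, str] | None:
    left = None
    right = None
    for b in aln.blocks:
        if b.q_end <= s and (left is None or b.q_end > left.q_end):
            left = b
        if b.q_start >= e and (right is None or b.q_start < right.q_start):
            right = b
    if left is not None:
        return (left.chrom_id, left.r_end, "left")
    if right is not None:
        return (right.chrom_id, right.r_start, "right")
    return None


def extract_candidates(
    results: dict[str, QueryResult],
    queries: list[SequenceRecord],
    min_novel_len: int = MIN_NOVEL_LEN_DEFAULT,
) -> list[NovelCandidate]:
    """Complement of the final aligned blocks within each query, with pure-N
    runs clipped out and pieces shorter than ``min_novel_len`` dropped."""
    by_id = {q.id: q for q in queries}
    out: list[NovelCandidate] = []
    for qid in sorted(results):
        res = results[qid]
        query = by_id[qid]
        runs = res.alignment.unaligned_runs()
        pieces = subtract(runs, list(query.n_runs))
        for s, e in pieces:
            if e - s < min_novel_len:
                continue
            out.append(
                NovelCandidate(
                    query_id=qid,
                    start=s,
                    end=e,
                    origin_length=query.length,
                    anchor=_nearest_anchor(res.alignment, s, e),
                )
            )
    return out


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output (outfmt 6).

    BLAST's 1-based inclusive query coordinates are converted to 0-based
    half-open; reverse-strand subject coordinates (start > end) are accepted
    and do not affect the query interval.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                identity = float(fields[2])
                qs, qe = int(fields[6]), int(fields[7])
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if qs > qe:
                qs, qe = qe, qs
            hits.append(BlastHit(qid, qs - 1, qe, sid, identity, evalue))
    return hits


def parse_repeatmasker_out(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Parse a RepeatMasker .out file (3 header lines, whitespace-delimited).

    Returns (query_id, q_start, q_end, repeat_class) with coordinates
    converted from 1-based inclusive to 0-based half-open; the repeat
    class/family string is kept verbatim.
    """
    rows: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= 3:  # banner, column names, blank line
                continue
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: too few columns for a RepeatMasker row")
            try:
                qid = fields[4]
                qs, qe = int(fields[5]), int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            rows.append((qid, qs - 1, qe, fields[10]))
    return rows


def blast_masks(hits: Iterable[BlastHit], source: str = "blast") -> list[Mask]:
    return [Mask(h.query_id, h.q_start, h.q_end, source, h.identity) for h in hits]


def repeat_masks(
    rows: Iterable[tuple[str, int, int, str]], source: str = "repeatmasker"
) -> list[Mask]:
    return [Mask(qid, s, e, source) for qid, s, e, _cls in rows]


@dataclass
class FilterReport:
    """Bookkeeping for one filter application."""

    filter_name: str
    removed_bases: int = 0
    refilter_dropped_bases: int = 0
    removed_by_source: dict[str, int] = field(default_factory=dict)
    unknown_mask_ids: list[str] = field(default_factory=list)


def subtract_and_refilter(
    candidates: list[NovelCandidate],
    masks: list[Mask],
    min_novel_len: int = MIN_NOVEL_LEN_DEFAULT,
    identity_ceiling: float | None = None,
    filter_name: str = "mask",
) -> tuple[list[NovelCandidate], FilterReport]:
    """Subtract mask intervals from candidates, then re-apply the minimum
    length filter.

    When ``identity_ceiling`` is given, masks with a recorded identity below
    it are ignored — a hit under the ceiling still counts as novel.  Masks
    naming candidates absent from the input are skipped and noted in the
    report.  Surviving pieces inherit the parent's metadata and an updated
    filter trail.
    """
    report = FilterReport(filter_name)
    known = {c.source_name for c in candidates}
    by_cand: dict[str, list[Mask]] = {}
    for m in masks:
        if m.candidate_id not in known:
            report.unknown_mask_ids.append(m.candidate_id)
            continue
        if identity_ceiling is not None and m.identity is not None and m.identity < identity_ceiling:
            continue
        by_cand.setdefault(m.candidate_id, []).append(m)

    out: list[NovelCandidate] = []
    for c in candidates:
        cmasks = by_cand.get(c.source_name)
        if not cmasks:
            out.append(c)
            continue
        # lift mask coordinates (local to the extracted candidate) onto the query
        mask_ivs = [(c.source_start + m.start, c.source_start + m.end) for m in cmasks]
        cur = [(c.start, c.end)]
        kept = subtract(cur, mask_ivs)
        removed = c.length - total_length(kept)
        report.removed_bases += removed
        for src in {m.source for m in cmasks}:
            src_ivs = [
                (c.source_start + m.start, c.source_start + m.end)
                for m in cmasks
                if m.source == src
            ]
            hit = total_length(intersect(cur, src_ivs))
            if hit:
                report.removed_by_source[src] = report.removed_by_source.get(src, 0) + hit
        for s, e in kept:
            if e - s < min_novel_len:
                report.refilter_dropped_bases += e - s
                continue
            trail = c.filter_trail + ((filter_name, removed),) if removed else c.filter_trail
            out.append(replace(c, start=s, end=e, filter_trail=trail))
    return out, report


def contamination_screen(
    candidates: list[NovelCandidate],
    contaminant_masks: list[Mask],
    min_novel_len: int = MIN_NOVEL_LEN_DEFAULT,
) -> tuple[list[NovelCandidate], dict[str, int]]:
    """Remove candidate bases matching labeled contaminant sources.

    No identity ceiling applies — contaminant hits are trusted as given.
    Returns the surviving candidates and a per-source tally of the removed
    bases.  With no masks this is an identity pass-through.
    """
    if not contaminant_masks:
        return list(candidates), {}
    kept, report = subtract_and_refilter(
        candidates, contaminant_masks, min_novel_len,
        identity_ceiling=None, filter_name="contamination",
    )
    return kept, dict(report.removed_by_source)


def base_accounting(
    before: list[NovelCandidate], after: list[NovelCandidate], report: FilterReport
) -> tuple[int, int]:
    """(input bases, output + removed + refilter-dropped bases); the two are
    equal when the filter conserved bases."""
    inp = sum(c.length for c in before)
    outp = sum(c.length for c in after) + report.removed_bases + report.refilter_dropped_bases
    return inp, outp


def write_candidates_tsv(candidates: list[NovelCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "name\tquery_id\tstart\tend\torigin_length\tanchor\t"
            "source_name\tsource_start\tfilter_trail\n"
        )
        for c in candidates:
            anchor = "unplaced" if c.anchor is None else f"{c.anchor[0]}:{c.anchor[1]}:{c.anchor[2]}"
            trail = ";".join(f"{n}={b}" for n, b in c.filter_trail) or "-"
            fh.write(
                f"{c.name}\t{c.query_id}\t{c.start}\t{c.end}\t{c.origin_length}\t"
                f"{anchor}\t{c.source_name}\t{c.source_start}\t{trail}\n"
            )


def read_candidates_tsv(path) -> list[NovelCandidate]:
    out: list[NovelCandidate] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            (_name, qid, s, e, origin, anchor, src_name, src_start, trail) = (
                line.rstrip("\n").split("\t")
            )
            anc = None
            if anchor != "unplaced":
                chrom, pos, side = anchor.rsplit(":", 2)
                anc = (chrom, int(pos), side)
            trail_t: tuple[tuple[str, int], ...] = ()
            if trail != "-":
                trail_t = tuple(
                    (p.split("=")[0], int(p.split("=")[1])) for p in trail.split(";")
                )
            out.append(
                NovelCandidate(
                    qid, int(s), int(e), int(origin), anc, trail_t, src_name, int(src_start)
                )
            )
    return out


def write_candidates_bed(candidates: list[NovelCandidate], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.query_id}\t{c.start}\t{c.end}\t{c.name}\n")


def write_candidates_fasta(
    candidates: list[NovelCandidate], queries: list[SequenceRecord], path
) -> None:
    """Candidate FASTA; headers carry the origin id, a 1-based inclusive
    interval, and the anchor, for downstream BLAST/RepeatMasker runs."""
    by_id = {q.id: q for q in queries}
    with open(path, "w") as fh:
        for c in candidates:
            anchor = "unplaced" if c.anchor is None else f"{c.anchor[0]}:{c.anchor[1] + 1}:{c.anchor[2]}"
            fh.write(f">{c.name} {c.query_id}:{c.start + 1}-{c.end} anchor={anchor}\n")
            seq = by_id[c.query_id].seq[c.start : c.end]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
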