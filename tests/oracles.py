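"""Independent brute-force oracles used to cross-check the aligner.

These deliberately avoid the package's hash-table / position-list-
intersection machinery: all matching is done by direct substring comparison
over every reference offset.
"""

from __future__ import annotations


def find_occurrences(ref: str, kmer: str, pred=None) -> list[int]:
    """All reference offsets whose window equals ``kmer`` (optionally
    restricted by ``pred``), by naive string comparison."""
    k = len(kmer)
    out = []
    for r in range(len(ref) - k + 1):
        if (pred is None or pred(r)) and ref[r : r + k] == kmer:
            out.append(r)
    return out


def chain_scan_oracle(
    ref: str,
    query: str,
    k: int,
    step: int,
    min_len: int,
    pred=None,
) -> list[tuple[int, int, int]]:
    """Greedy left-to-right maximal-unique chain enumeration by brute force.

    Mirrors the scan semantics — seeds ``step`` apart, chains narrowed until
    a unique reference location survives, restart after each chain, one seed
    lookup per base — but finds candidate positions by scanning every
    reference offset directly.  Returns (q_start, q_end, r_start) tuples.
    """
    regions: list[tuple[int, int, int]] = []
    n = len(query) - k + 1
    q = 0
    while q < n:
        kmer = query[q : q + k]
        if "N" in kmer:
            q += 1
            continue
        cands = find_occurrences(ref, kmer, pred)
        if not cands:
            q += 1
            continue
        t = 1
        while True:
            nq = q + t * step
            if nq >= n:
                break
            kmer2 = query[nq : nq + k]
            if "N" in kmer2:
                break
            nxt = [
                r
                for r in cands
                if r + t * step + k <= len(ref)
                and ref[r + t * step : r + t * step + k] == kmer2
            ]
            if not nxt:
                break
            cands = nxt
            t += 1
        span = (t - 1) * step + k
        if len(cands) == 1 and span >= min_len:
            regions.append((q, q + span, cands[0]))
        q += span
    return regions


def kmer_multiset(seq: str, k: int) -> dict[str, list[int]]:
    """Direct enumeration of all N-free k-mer windows and their positions."""
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            out.setdefault(w, []).append(i)
    return out
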