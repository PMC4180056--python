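"""Minimal interval arithmetic on sorted 0-based half-open (start, end) lists."""

from __future__ import annotations

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Union of intervals as a sorted disjoint list; empty intervals dropped."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def complement(intervals: list[Interval], length: int) -> list[Interval]:
    """Gaps of [0, length) not covered by ``intervals``."""
    out: list[Interval] = []
    cur = 0
    for s, e in merge(intervals):
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out


def subtract(intervals: list[Interval], masks: list[Interval]) -> list[Interval]:
    """Parts of ``intervals`` not covered by ``masks`` (both need not be sorted)."""
    masks = merge(masks)
    out: list[Interval] = []
    for s, e in merge(intervals):
        cur = s
        for ms, me in masks:
            if me <= cur:
                continue
            if ms >= e:
                break
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))
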