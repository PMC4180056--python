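"""Comparison viewer for novel-sequence candidates.

Candidates are laid out left to right in ascending order of the length of
their originating contig/scaffold (so contig-derived candidates sit left of
scaffold-derived ones), with each candidate's width proportional to its
base count.  One colored row per comparison set shows, per candidate, the
fraction of its bases covered by that set's masks; dashed vertical guides
mark deciles of the origin-length rank.  Runs of candidates with no
coverage in any track stand out as empty columns — the visual signature of
contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from nsit._intervals import intersect, total_length
from nsit.novel_candidates import Mask, NovelCandidate

__all__ = ["OverlapTrack", "CandidateLayout", "layout_candidates", "make_track", "render"]


@dataclass
class OverlapTrack:
    """Per-candidate coverage fractions for one comparison set."""

    label: str
    covered: list[float]
    color: str = "tab:blue"

    def __post_init__(self) -> None:
        bad = [f for f in self.covered if not 0.0 <= f <= 1.0]
        if bad:
            raise ValueError(f"coverage fractions outside [0, 1]: {bad[:3]}")


@dataclass
class CandidateLayout:
    """Candidates in display order with cumulative-base x positions."""

    candidates: list[NovelCandidate]
    x_starts: list[int]
    total_bases: int
    decile_ticks: list[int] = field(default_factory=list)


def layout_candidates(candidates: list[NovelCandidate]) -> CandidateLayout:
    """Stable ascending sort by originating-sequence length (ties by
    candidate id); x positions accumulate candidate bases; decile guides sit
    at every tenth of the origin-length rank."""
    if not candidates:
        warnings.warn("no candidates to lay out; plot will be empty")
        return CandidateLayout([], [], 0)
    ordered = sorted(candidates, key=lambda c: (c.origin_length, c.name))
    x_starts: list[int] = []
    x = 0
    for c in ordered:
        x_starts.append(x)
        x += c.length
    n = len(ordered)
    ticks = []
    for d in range(1, 10):
        idx = (d * n) // 10
        if 0 < idx < n:
            ticks.append(x_starts[idx])
    return CandidateLayout(ordered, x_starts, x, sorted(set(ticks)))


def make_track(
    label: str,
    layout: CandidateLayout,
    masks: list[Mask],
    color: str = "tab:blue",
) -> OverlapTrack:
    """Coverage fractions computed from the same parsed mask files used by
    the filtering stage (masks are local to each extracted candidate)."""
    by_cand: dict[str, list[tuple[int, int]]] = {}
    for m in masks:
        by_cand.setdefault(m.candidate_id, []).append((m.start, m.end))
    fractions = []
    for c in layout.candidates:
        ivs = by_cand.get(c.source_name, [])
        # candidate extent in source-local coordinates
        lo = c.start - c.source_start
        hi = c.end - c.source_start
        covered = total_length(intersect([(lo, hi)], ivs))
        fractions.append(covered / c.length if c.length else 0.0)
    return OverlapTrack(label, fractions, color)


def render(
    tracks: list[OverlapTrack],
    layout: CandidateLayout,
    path: str,
    dpi: int = 150,
) -> None:
    """Write the comparison figure (PNG or SVG, by file extension).

    One row per track; within a row, each candidate is drawn as a bar whose
    height is its coverage fraction, so uncovered candidates leave visible
    gaps.  Deterministic canvas: fixed size, no fonts required beyond
    matplotlib defaults.
    """
    if not tracks:
        raise ValueError("render requires at least one track")
    for t in tracks:
        if len(t.covered) != len(layout.candidates):
            raise ValueError(
                f"track {t.label!r} has {len(t.covered)} fractions for "
                f"{len(layout.candidates)} candidates"
            )
    n_tracks = len(tracks)
    fig, axes = plt.subplots(
        n_tracks, 1, sharex=True, figsize=(10, 1.2 * n_tracks + 0.8), squeeze=False
    )
    for row, track in enumerate(tracks):
        ax = axes[row][0]
        for c, x, frac in zip(layout.candidates, layout.x_starts, track.covered):
            if frac > 0:
                ax.add_patch(
                    plt.Rectangle((x, 0), c.length, frac, color=track.color, linewidth=0)
                )
        for tick in layout.decile_ticks:
            ax.axvline(tick, linestyle="--", linewidth=0.5, color="grey")
        ax.set_xlim(0, max(layout.total_bases, 1))
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel(track.label, rotation=0, ha="right", va="center", fontsize=8)
    axes[-1][0].set_xlabel("cumulative candidate bases (origin length ascending)")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
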