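"""Reference regions covered by no contig, and their consistency across runs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .misassembly import AlignmentBlock

__all__ = ["GapInterval", "find_gaps", "total_gap_length", "gap_consistency"]


@dataclass(frozen=True, order=True)
class GapInterval:
    """Maximal uncovered replicon interval, 0-based half-open."""

    replicon_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("gap interval must be non-empty")


def find_gaps(blocks: Sequence[AlignmentBlock],
              replicon_len: int, replicon_id: str | None = None
              ) -> list[GapInterval]:
    """Complement of the union of block target intervals on one replicon."""
    if replicon_len <= 0:
        raise ValueError("replicon length must be positive")
    if replicon_id is None:
        replicon_id = blocks[0].replicon_id if blocks else ""
    ivals = sorted((b.t_start, b.t_end) for b in blocks)
    gaps: list[GapInterval] = []
    cursor = 0
    for s, e in ivals:
        if s > cursor:
            gaps.append(GapInterval(replicon_id, cursor, s))
        cursor = max(cursor, e)
    if cursor < replicon_len:
        gaps.append(GapInterval(replicon_id, cursor, replicon_len))
    return gaps


def total_gap_length(gaps: Sequence[GapInterval]) -> int:
    """Sum of gap sizes; the intervals must be disjoint."""
    by_rep: dict[str, list[GapInterval]] = {}
    for g in gaps:
        by_rep.setdefault(g.replicon_id, []).append(g)
    for ivals in by_rep.values():
        ivals.sort()
        for a, b in zip(ivals, ivals[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping gap intervals on "
                                 f"{a.replicon_id}: {a} and {b}")
    return sum(g.end - g.start for g in gaps)


def _matches(g: GapInterval, pool: Sequence[GapInterval], tol: int) -> bool:
    return any(h.replicon_id == g.replicon_id
               and abs(h.start - g.start) <= tol
               and abs(h.end - g.end) <= tol for h in pool)


def gap_consistency(runs: Sequence[Sequence[GapInterval]], tolerance: int = 0
                    ) -> tuple[list[GapInterval], dict[GapInterval, int]]:
    """Partition gaps into those present in every run and the rest.

    A gap is consistent iff every run contains a gap on the same replicon
    whose endpoints both lie within ``tolerance`` bases of it.  Gaps not in
    all runs are keyed by the number of runs containing them.
    """
    if len(runs) < 2:
        raise ValueError("gap consistency needs at least 2 runs")
    all_gaps: list[GapInterval] = []
    seen: set[GapInterval] = set()
    for run in runs:
        for g in run:
            if g not in seen:
                seen.add(g)
                all_gaps.append(g)
    consistent: list[GapInterval] = []
    partial: dict[GapInterval, int] = {}
    for g in all_gaps:
        count = sum(1 for run in runs if _matches(g, run, tolerance))
        if count == len(runs):
            if not _matches(g, consistent, tolerance):
                consistent.append(g)
        else:
            partial[g] = count
    return consistent, partial
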