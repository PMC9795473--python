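"""Global assembly metrics over the original and length-filtered contig sets.

The filtered set (FS) keeps contigs of at least ``min_contig_len`` bases
(default 1,000 bp, the tool's default minimum contig size; >= semantics as
in BBTools ``minlength``).  Two global statistics — misassembled contigs
and total gap size — are consolidations of the per-replicon reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence

from .io import SequenceRecord

if TYPE_CHECKING:  # pragma: no cover
    from .reference import PerReferenceReport

__all__ = ["FilterConfig", "AssemblyStats", "filter_contigs", "n50",
           "global_stats", "count_uncalled", "consolidate"]

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class FilterConfig:
    min_contig_len: int = 1000

    def __post_init__(self) -> None:
        if self.min_contig_len < 0:
            raise ValueError("min_contig_len must be >= 0")


@dataclass
class AssemblyStats:
    n_contigs: int = 0
    total_bp: int = 0
    largest_contig: int = 0
    n50: int = 0
    uncalled: int = 0
    mapped_read_fraction: Optional[float] = None
    misassembled_contigs: Optional[int] = None
    misassembly_events: Optional[int] = None
    total_gap_bp: Optional[int] = None


def filter_contigs(contigs: Sequence[SequenceRecord],
                   cfg: FilterConfig = FilterConfig()
                   ) -> list[SequenceRecord]:
    """Keep contigs with length >= min_contig_len, preserving order."""
    return [c for c in contigs if c.length >= cfg.min_contig_len]


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L such that contigs >= L hold half the total bases."""
    if not lengths:
        raise ValueError("N50 of an empty length set is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if 2 * acc >= total:
            return l
    raise AssertionError("unreachable")  # pragma: no cover


def count_uncalled(seq: str, n_only: bool = False) -> int:
    """Bases outside {A,C,G,T} (N and IUPAC ambiguity codes).

    ``n_only`` restricts the count to literal N, for callers that treat
    other ambiguity codes as called bases.
    """
    if n_only:
        return seq.count("N")
    return sum(1 for b in seq if b not in _ACGT)


def global_stats(contigs: Sequence[SequenceRecord]) -> AssemblyStats:
    """Contig-set statistics; an empty assembly yields all-zero stats
    (rendered downstream as the failed-assembler warning, not an error)."""
    if not contigs:
        return AssemblyStats()
    lengths = [c.length for c in contigs]
    return AssemblyStats(
        n_contigs=len(contigs),
        total_bp=sum(lengths),
        largest_contig=max(lengths),
        n50=n50(lengths),
        uncalled=sum(count_uncalled(c.seq) for c in contigs),
    )


def consolidate(per_ref: Sequence["PerReferenceReport"]
                ) -> tuple[int, int, int]:
    """(misassembled contigs, misassembly events, total gap bp) across all
    replicon reports; a chimera spanning two replicons counts once."""
    contig_ids: set[str] = set()
    events = 0
    seen_event_keys: set[tuple] = set()
    gap_bp = 0
    for rep in per_ref:
        for call in rep.misassembly_calls:
            if call.categories:
                contig_ids.add(call.contig_id)
            for ev in call.events:
                key = (call.contig_id, ev.category,
                       ev.block_a.q_start, ev.block_a.q_end,
                       None if ev.block_b is None else ev.block_b.q_start)
                if key not in seen_event_keys:
                    seen_event_keys.add(key)
                    events += 1
        gap_bp += sum(g.end - g.start for g in rep.gaps)
    return len(contig_ids), events, gap_bp
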