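"""Cross-run contig consistency: contigs matched across runs by size.

Matching by exact length is deliberately coarse — two genuinely different
contigs of equal length are indistinguishable to it — but it needs nothing
beyond the per-run FASTA and directly measures whether an assembler emits
the same contig set run after run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

__all__ = ["RunComparison", "match_by_size", "inconsistency_rate"]


@dataclass
class RunComparison:
    n_runs: int
    total_contigs: int
    in_all: int
    in_two: int
    in_one: int

    @property
    def inconsistent_fraction(self) -> float:
        if self.total_contigs == 0:
            raise ValueError("no contigs to compare")
        return (self.in_two + self.in_one) / self.total_contigs


def match_by_size(runs: Sequence[Sequence[int]]) -> RunComparison:
    """Multiset-match contig lengths across runs.

    Counts are over matched contig *entities*: for each distinct length,
    the minimum per-run copy count gives contigs present in every run;
    remaining copies are matched greedily across run pairs (one entity per
    matched pair of copies); leftovers are contigs seen in a single run.
    ``total_contigs`` is the number of copies over all runs (the
    denominator of the inconsistency fraction).
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to compare")
    counters = [Counter(run) for run in runs]
    lengths = set().union(*counters)
    in_all = in_two = in_one = 0
    for l in lengths:
        counts = [c[l] for c in counters]
        base = min(counts)
        in_all += base
        residual = sorted((c - base for c in counts), reverse=True)
        # pair leftover copies two runs at a time; each pair is one contig
        while len(residual) >= 2 and residual[1] > 0:
            paired = residual[1]
            in_two += paired
            residual[0] -= paired
            residual[1] = 0
            residual.sort(reverse=True)
        in_one += sum(residual)
    total = sum(sum(c.values()) for c in counters)
    return RunComparison(n_runs=len(runs), total_contigs=total,
                         in_all=in_all, in_two=in_two, in_one=in_one)


def inconsistency_rate(cmp: RunComparison) -> float:
    """Fraction of all contigs (over all runs) present in only 1 or 2 runs."""
    return cmp.inconsistent_fraction
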