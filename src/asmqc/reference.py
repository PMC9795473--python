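"""Per-replicon metrics on the filtered contig set.

For each reference replicon: breadth of coverage, number of aligned
contigs and bases, mismatches (SNPs), uncalled bases in aligned regions,
the COMPASS ratios (coverage, validity, multiplicity, parsimony), and the
two contig-level scores

* **LSA** — the fraction of the longest single contig-to-reference
  alignment relative to the replicon length;
* **Pls** — a Phred-like score of contig identity,
  ``Pls = -10 * log10(E)`` for ``0 < E <= 1`` and ``60`` for ``E = 0``,
  where ``E = 1 - identity``.  Like a Phred base quality, Pls 20 means one
  error per 100 aligned columns; a perfect contig scores the cap of 60.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .gaps import GapInterval, find_gaps
from .io import AlignmentRecord, SequenceRecord
from .metrics import count_uncalled
from .misassembly import (AlignmentBlock, ClassifierThresholds,
                          MisassemblyCall, blocks_from_alignments, classify)

__all__ = ["PLS_CAP", "ContigAlignmentSummary", "CompassMetrics",
           "PerReferenceReport", "phred_like", "breadth_of_coverage", "lsa",
           "mismatch_count", "compass", "gc_content", "per_reference_report",
           "build_reports"]

#: Score assigned to a perfectly identical contig (E = 0).
PLS_CAP = 60.0


def phred_like(error: float) -> float:
    """Phred-like score of an error fraction ``E = 1 - identity``.

    ``-10 * log10(E)`` on ``0 < E <= 1``; exactly 60 at ``E = 0``.
    """
    if not 0.0 <= error <= 1.0:
        raise ValueError(f"error fraction must be in [0, 1], got {error}")
    if error == 0.0:
        return PLS_CAP
    return -10.0 * math.log10(error)


@dataclass
class ContigAlignmentSummary:
    """One contig's aggregate alignment to one replicon."""

    contig_id: str
    contig_len: int
    n_match: int
    aln_cols: int
    mismatches: Optional[int]

    @property
    def identity(self) -> float:
        return self.n_match / self.aln_cols if self.aln_cols else 0.0

    @property
    def pls(self) -> float:
        return phred_like(1.0 - self.identity)


@dataclass
class CompassMetrics:
    coverage: float
    validity: float
    multiplicity: float
    parsimony: float


@dataclass
class PerReferenceReport:
    replicon_id: str
    replicon_len: int
    gc: float
    n_contigs_aligned: int
    aligned_bp: int
    breadth: float
    lsa: float
    snps: Optional[int]
    uncalled_aligned: int
    compass: CompassMetrics
    contig_summaries: list[ContigAlignmentSummary]
    gaps: list[GapInterval]
    misassembly_calls: list[MisassemblyCall]

    @property
    def no_alignment(self) -> bool:
        """The failed-assembler case: nothing aligned to this replicon."""
        return self.n_contigs_aligned == 0


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    cursor = -1
    for s, e in sorted(intervals):
        if s > cursor:
            total += e - s
            cursor = e
        elif e > cursor:
            total += e - cursor
            cursor = e
    return total


def breadth_of_coverage(blocks: Sequence[AlignmentBlock],
                        replicon_len: int) -> float:
    """|union of block target intervals| / replicon length."""
    if replicon_len <= 0:
        raise ValueError("replicon length must be positive")
    return _union_length([(b.t_start, b.t_end) for b in blocks]) / replicon_len


def lsa(blocks: Sequence[AlignmentBlock], replicon_len: int) -> float:
    """Longest single alignment as a fraction of the replicon length."""
    if replicon_len <= 0:
        raise ValueError("replicon length must be positive")
    if not blocks:
        return 0.0
    return max(b.t_end - b.t_start for b in blocks) / replicon_len


def _block_mismatches(block: AlignmentBlock) -> Optional[int]:
    """Substitution count of one block, or None when unrecoverable.

    With an extended CIGAR the X columns are counted directly.  M-only
    CIGARs cannot localise substitutions; indel bases are subtracted from
    the record-level edit distance when one is carried.
    """
    if block.cigar is not None:
        if any(o.op == "X" for o in block.cigar) or \
                all(o.op in "=ID" for o in block.cigar):
            return sum(o.run for o in block.cigar if o.op == "X")
    return None


def mismatch_count(blocks: Sequence[AlignmentBlock],
                   records: Sequence[AlignmentRecord] = ()) -> Optional[int]:
    """Total substitutions over blocks; None when any block cannot say.

    Blocks from extended CIGARs count X columns.  For records with only an
    M-CIGAR (or none) plus an NM tag, substitutions are recovered as
    ``NM - inserted - deleted`` at the record level.  A block with neither
    makes the total unreportable (None), never silently zero.
    """
    total = 0
    fallback: dict[int, Optional[int]] = {}
    for rec in records:
        if rec.nm is not None:
            indels = 0
            if rec.cigar is not None:
                indels = sum(o.run for o in rec.cigar if o.op in "ID")
            fallback[id(rec)] = rec.nm - indels
        else:
            fallback[id(rec)] = None

    per_record_used: set[int] = set()
    for b in blocks:
        m = _block_mismatches(b)
        if m is not None:
            total += m
            continue
        # fall back to the parent record's NM-derived count once per record
        matched = None
        for rec in records:
            if rec.query_id == b.contig_id and rec.target_id == b.replicon_id \
                    and rec.target_start <= b.t_start and b.t_end <= rec.target_end:
                matched = rec
                break
        if matched is None or fallback.get(id(matched)) is None:
            return None
        if id(matched) not in per_record_used:
            per_record_used.add(id(matched))
            total += fallback[id(matched)]
    return total


def compass(blocks: Sequence[AlignmentBlock], replicon_len: int,
            fs_total_bp: int) -> CompassMetrics:
    """COMPASS ratios for one replicon.

    coverage = covered reference bases / replicon length;
    validity = aligned query bases / total filtered-set bases assigned to
    this replicon; multiplicity = aligned query bases / covered reference
    bases; parsimony = multiplicity / validity.  Overlapping blocks
    double-count aligned query bases (redundancy is the point of
    multiplicity) but not covered reference bases.
    """
    if replicon_len <= 0:
        raise ValueError("replicon length must be positive")
    covered = _union_length([(b.t_start, b.t_end) for b in blocks])
    aligned_q = sum(b.q_end - b.q_start for b in blocks)
    coverage = covered / replicon_len
    validity = aligned_q / fs_total_bp if fs_total_bp else 0.0
    multiplicity = aligned_q / covered if covered else 0.0
    parsimony = multiplicity / validity if validity else 0.0
    return CompassMetrics(coverage=coverage, validity=validity,
                          multiplicity=multiplicity, parsimony=parsimony)


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); uncalled bases are excluded from the denominator."""
    gc = sum(1 for b in seq if b in "GC")
    acgt = sum(1 for b in seq if b in "ACGT")
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / acgt


def _aligned_uncalled(blocks: Sequence[AlignmentBlock],
                      contigs_by_id: dict[str, SequenceRecord]) -> int:
    total = 0
    for b in blocks:
        contig = contigs_by_id.get(b.contig_id)
        if contig is not None:
            total += count_uncalled(contig.seq[b.q_start:b.q_end])
    return total


def per_reference_report(replicon: SequenceRecord,
                         fs_contigs: Sequence[SequenceRecord],
                         alignments: Sequence[AlignmentRecord],
                         thresholds: ClassifierThresholds = ClassifierThresholds()
                         ) -> PerReferenceReport:
    """All per-replicon metrics for one replicon of one assembly.

    ``alignments`` must already be restricted to filtered-set contigs; the
    blocks and misassembly calls are derived here.  Contigs with no block
    on this replicon do not appear in the contig summaries.
    """
    contigs_by_id = {c.id: c for c in fs_contigs}
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for rec in alignments:
        by_contig.setdefault(rec.query_id, []).append(rec)

    blocks_here: list[AlignmentBlock] = []
    calls: list[MisassemblyCall] = []
    for contig_id in sorted(by_contig):
        all_blocks = blocks_from_alignments(by_contig[contig_id], thresholds)
        call = classify(all_blocks, thresholds)
        mine = [b for b in all_blocks if b.replicon_id == replicon.id]
        if not mine:
            continue
        blocks_here.extend(mine)
        if call.categories:
            calls.append(call)

    summaries: list[ContigAlignmentSummary] = []
    per_contig: dict[str, list[AlignmentBlock]] = {}
    for b in blocks_here:
        per_contig.setdefault(b.contig_id, []).append(b)
    for contig_id in sorted(per_contig):
        bl = per_contig[contig_id]
        recs = [r for r in by_contig[contig_id]
                if r.target_id == replicon.id and r.is_primary]
        mm = mismatch_count(bl, recs)
        summaries.append(ContigAlignmentSummary(
            contig_id=contig_id,
            contig_len=contigs_by_id[contig_id].length
            if contig_id in contigs_by_id else 0,
            n_match=sum(b.n_match for b in bl),
            aln_cols=sum(b.aln_cols for b in bl),
            mismatches=mm))

    snps: Optional[int] = 0
    for s in summaries:
        if s.mismatches is None:
            snps = None
            break
        snps += s.mismatches

    # validity denominator: filtered-set bases of contigs whose primary
    # alignment lies on this replicon
    fs_assigned = 0
    for contig_id, recs in by_contig.items():
        primaries = [r for r in recs if r.is_primary]
        if not primaries:
            continue
        best = max(primaries, key=lambda r: r.n_match)
        if best.target_id == replicon.id and contig_id in contigs_by_id:
            fs_assigned += contigs_by_id[contig_id].length

    return PerReferenceReport(
        replicon_id=replicon.id,
        replicon_len=replicon.length,
        gc=gc_content(replicon.seq),
        n_contigs_aligned=len(per_contig),
        aligned_bp=sum(b.q_end - b.q_start for b in blocks_here),
        breadth=breadth_of_coverage(blocks_here, replicon.length),
        lsa=lsa(blocks_here, replicon.length),
        snps=snps,
        uncalled_aligned=_aligned_uncalled(blocks_here, contigs_by_id),
        compass=compass(blocks_here, replicon.length, fs_assigned),
        contig_summaries=summaries,
        gaps=find_gaps(blocks_here, replicon.length, replicon.id),
        misassembly_calls=calls,
    )


def build_reports(replicons: Sequence[SequenceRecord],
                  fs_contigs: Sequence[SequenceRecord],
                  alignments: Sequence[AlignmentRecord],
                  thresholds: ClassifierThresholds = ClassifierThresholds()
                  ) -> list[PerReferenceReport]:
    """Per-replicon reports for every replicon of the community."""
    return [per_reference_report(rep, fs_contigs, alignments, thresholds)
            for rep in replicons]
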