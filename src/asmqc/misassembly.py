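"""Misassembly detection: split alignments into blocks, classify contigs.

A contig whose filtered-set alignments break into multiple blocks is
interrogated block-pair by block-pair.  Categories: chimera (blocks on two
or more distinct replicons — exclusive: no further classification),
insertion, deletion, inversion, rearrangement, translocation, duplication,
and the fallback "inconsistent" for multi-block contigs where no rule
fires.  Magnitude thresholds are conventions of this tool (1 kb for
translocation follows the relocation convention popularised by QUAST); the
taxonomy itself gives none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .io import AlignmentRecord, CigarOp

__all__ = ["AlignmentBlock", "ClassifierThresholds", "MisassemblyCall",
           "MisassemblyEvent", "blocks_from_alignments", "classify",
           "summarize", "CATEGORIES"]

CATEGORIES = ("chimera", "insertion", "deletion", "inversion",
              "rearrangement", "translocation", "duplication", "inconsistent")


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned block of a contig on one replicon.

    ``q_start``/``q_end`` are on the forward contig, 0-based half-open;
    ``t_start``/``t_end`` likewise on the forward replicon.  Blocks are the
    atomic unit of misassembly classification.
    """

    contig_id: str
    q_start: int
    q_end: int
    strand: str
    replicon_id: str
    t_start: int
    t_end: int
    n_match: int
    aln_cols: int
    cigar: Optional[tuple[CigarOp, ...]] = None

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.t_start < self.t_end):
            raise ValueError("block intervals must be non-empty")


@dataclass(frozen=True)
class ClassifierThresholds:
    """Magnitude thresholds of the block classifier, in bases."""

    block_split_indel: int = 50
    ins_min: int = 50
    del_min: int = 50
    dup_overlap_min: int = 50
    trans_min: int = 1000

    def __post_init__(self) -> None:
        for name in ("block_split_indel", "ins_min", "del_min",
                     "dup_overlap_min", "trans_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MisassemblyEvent:
    category: str
    block_a: AlignmentBlock
    block_b: Optional[AlignmentBlock]
    magnitude: int


@dataclass
class MisassemblyCall:
    contig_id: str
    categories: frozenset[str]
    events: list[MisassemblyEvent] = field(default_factory=list)


#: '=' run length treated as a reliable anchor when deciding whether the
#: scattered indels between two anchors amount to one structural event.
#: A 20 bp exact match arises by chance once per ~10^12 random columns, so
#: spurious micro-matches inside an inserted/deleted region never anchor.
_SPLIT_ANCHOR_MIN = 20


def _split_record(rec: AlignmentRecord,
                  th: ClassifierThresholds) -> list[AlignmentBlock]:
    """Split one alignment record where the *net* indel between reliable
    anchors reaches block_split_indel.

    Aligners spread a large inserted (or deleted) stretch over many small
    indel runs interleaved with coincidental micro-matches; summing the
    net query-minus-target consumption between long exact-match anchors
    recovers the event regardless of that fragmentation.  Cursors walk
    the CIGAR in the alignment frame (rc-query for '-' records); query
    coordinates are mapped back to the forward contig at the end.
    """
    if rec.cigar is None:
        return [AlignmentBlock(
            contig_id=rec.query_id, q_start=rec.query_start,
            q_end=rec.query_end, strand=rec.strand,
            replicon_id=rec.target_id, t_start=rec.target_start,
            t_end=rec.target_end, n_match=rec.n_match,
            aln_cols=rec.aln_cols, cigar=None)]

    # alternate runs of anchor ops and the (possibly junky) gaps between
    groups: list[tuple[bool, list[CigarOp]]] = []
    for op in rec.cigar:
        is_anchor = op.op == "=" and op.run >= _SPLIT_ANCHOR_MIN
        if groups and groups[-1][0] == is_anchor:
            groups[-1][1].append(op)
        else:
            groups.append((is_anchor, [op]))

    segments: list[tuple[int, int, int, int, list[CigarOp]]] = []
    q = t = 0  # alignment-frame offsets
    seg_q0, seg_t0 = 0, 0
    seg_ops: list[CigarOp] = []

    def consume(ops: list[CigarOp]) -> None:
        nonlocal q, t
        for o in ops:
            if o.op in "=XIM":
                q += o.run
            if o.op in "=XDM":
                t += o.run

    for is_anchor, ops in groups:
        if not is_anchor:
            qc = sum(o.run for o in ops if o.op in "=XIM")
            tc = sum(o.run for o in ops if o.op in "=XDM")
            if abs(qc - tc) >= th.block_split_indel:
                # close the current block; the junk joins neither side
                if seg_ops:
                    segments.append((seg_q0, q, seg_t0, t, seg_ops))
                consume(ops)
                seg_q0, seg_t0 = q, t
                seg_ops = []
                continue
        seg_ops.extend(ops)
        consume(ops)
    if seg_ops:
        segments.append((seg_q0, q, seg_t0, t, seg_ops))

    blocks = []
    for q0, q1, t0, t1, ops in segments:
        if q1 == q0 or t1 == t0:
            continue  # a segment that is pure indel remnant
        if rec.strand == "+":
            fq0 = rec.query_start + q0
            fq1 = rec.query_start + q1
        else:
            fq0 = rec.query_end - q1
            fq1 = rec.query_end - q0
        n_match = sum(o.run for o in ops if o.op == "=")
        blocks.append(AlignmentBlock(
            contig_id=rec.query_id, q_start=fq0, q_end=fq1,
            strand=rec.strand, replicon_id=rec.target_id,
            t_start=rec.target_start + t0, t_end=rec.target_start + t1,
            n_match=n_match, aln_cols=sum(o.run for o in ops),
            cigar=tuple(ops)))
    return blocks


def blocks_from_alignments(records: Sequence[AlignmentRecord],
                           th: ClassifierThresholds = ClassifierThresholds()
                           ) -> list[AlignmentBlock]:
    """Blocks for one contig: primary records split at large indels.

    Output is sorted by position on the forward contig.
    """
    blocks: list[AlignmentBlock] = []
    for rec in records:
        if not rec.is_primary:
            continue
        blocks.extend(_split_record(rec, th))
    blocks.sort(key=lambda b: (b.q_start, b.q_end, b.replicon_id, b.t_start))
    return blocks


def _oriented_gap(a: AlignmentBlock, b: AlignmentBlock) -> int:
    """Signed target gap between adjacent same-strand blocks, measured in
    the direction of travel along the contig."""
    if a.strand == "+":
        return b.t_start - a.t_end
    return a.t_start - b.t_end


def _target_overlap(a: AlignmentBlock, b: AlignmentBlock) -> int:
    return min(a.t_end, b.t_end) - max(a.t_start, b.t_start)


def classify(blocks: Sequence[AlignmentBlock],
             th: ClassifierThresholds = ClassifierThresholds()
             ) -> MisassemblyCall:
    """Classify one contig's block set.

    Blocks must be sorted by forward-contig coordinate.  A chimera verdict
    (blocks on >= 2 replicons) is exclusive and ends classification.  All
    other rules run on every adjacent block pair and may combine; a
    multi-block contig where nothing fires is "inconsistent".
    """
    if not blocks:
        return MisassemblyCall(contig_id="", categories=frozenset())
    contig_id = blocks[0].contig_id
    if any(b.contig_id != contig_id for b in blocks):
        raise ValueError("classify expects blocks from a single contig")
    starts = [b.q_start for b in blocks]
    if starts != sorted(starts):
        raise ValueError("blocks must be sorted by contig coordinate")
    if len(blocks) == 1:
        return MisassemblyCall(contig_id=contig_id, categories=frozenset())

    replicons = {b.replicon_id for b in blocks}
    if len(replicons) >= 2:
        ev = MisassemblyEvent("chimera", blocks[0], blocks[-1], 0)
        return MisassemblyCall(contig_id=contig_id,
                               categories=frozenset({"chimera"}),
                               events=[ev])

    events: list[MisassemblyEvent] = []
    for a, b in zip(blocks, blocks[1:]):
        if a.strand != b.strand:
            events.append(MisassemblyEvent("inversion", a, b,
                                           b.q_end - b.q_start))
            continue
        contig_gap = b.q_start - a.q_end
        target_gap = _oriented_gap(a, b)
        overlap = _target_overlap(a, b)
        if contig_gap >= th.ins_min and target_gap < th.ins_min:
            events.append(MisassemblyEvent("insertion", a, b, contig_gap))
        if th.del_min <= target_gap < th.trans_min and contig_gap < th.del_min:
            events.append(MisassemblyEvent("deletion", a, b, target_gap))
        if target_gap >= th.trans_min:
            events.append(MisassemblyEvent("translocation", a, b, target_gap))
        if overlap >= th.dup_overlap_min:
            events.append(MisassemblyEvent("duplication", a, b, overlap))
        monotonic = (b.t_start >= a.t_start if a.strand == "+"
                     else b.t_start <= a.t_start)
        if not monotonic:
            events.append(MisassemblyEvent("rearrangement", a, b,
                                           abs(b.t_start - a.t_start)))
    if not events:
        span = blocks[-1].q_end - blocks[0].q_start
        events.append(MisassemblyEvent("inconsistent", blocks[0],
                                       blocks[-1], span))
    return MisassemblyCall(contig_id=contig_id,
                           categories=frozenset(e.category for e in events),
                           events=events)


def summarize(calls: Sequence[MisassemblyCall]
              ) -> tuple[int, int, dict[str, int]]:
    """Counts over one call per contig: (misassembled contigs, events,
    events per category)."""
    misassembled = 0
    n_events = 0
    per_category: dict[str, int] = {}
    for call in calls:
        if call.categories:
            misassembled += 1
        n_events += len(call.events)
        for ev in call.events:
            per_category[ev.category] = per_category.get(ev.category, 0) + 1
    return misassembled, n_events, per_category
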