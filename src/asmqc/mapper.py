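"""Built-in contig-to-reference mapper (seed, chain, extend).

A deliberately small k-mer seed index plus co-linear chaining and
edit-distance gap closing (edlib), producing PAF-style alignment records
with extended CIGARs.  It exists so the whole evaluation pipeline runs at
desk scale with no external aligner binary; precomputed PAF from an
external mapper can always be substituted upstream.

The index stores every reference k-mer as a 2-bit-packed integer in a
sorted array; queries are looked up on both strands (the reverse strand by
encoding the reverse-complemented query, PAF-style, so the CIGAR of a
``-`` record describes rc(query) versus the forward target).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import numpy as np

from .io import (AlignmentRecord, SequenceRecord, cigar_query_len,
                 cigar_target_len, parse_cigar, reverse_complement)

__all__ = ["MapperParams", "SeedIndex", "index_reference", "map_query",
           "map_reads"]

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class MapperParams:
    """Tunable knobs of the built-in mapper.

    ``k``: seed k-mer size.  ``seed_stride``: sampling stride of query
    k-mers (reference k-mers are always indexed densely).  Chains need
    ``min_chain_seeds`` co-linear anchors within ``max_seed_gap`` of each
    other (in query, target, and diagonal).  Alignments spanning fewer than
    ``min_block_len`` query bases are suppressed.  The match/mismatch
    scores drive X-drop end extension only; gap closing between anchors is
    exact edit distance.
    """

    k: int = 15
    seed_stride: int = 3
    min_chain_seeds: int = 3
    max_seed_gap: int = 100
    min_block_len: int = 100
    match_score: int = 1
    mismatch_score: int = -2
    xdrop: int = 12
    max_hits_per_seed: int = 1000

    def __post_init__(self) -> None:
        if self.k < 7:
            raise ValueError("k must be >= 7")
        for name in ("seed_stride", "min_chain_seeds", "max_seed_gap",
                     "min_block_len", "xdrop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _encode_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit-pack all k-mers of ``seq``.

    Returns ``(codes, valid)`` of length ``len(seq) - k + 1``; windows
    containing any non-ACGT base are flagged invalid.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes4 = _BASE_CODE[raw]
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes4[j:j + n].astype(np.uint64)
    bad = (codes4 > 3).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    # invalid windows carry garbage 2-bit codes; mask them out
    return out, valid


@dataclass
class SeedIndex:
    """Sorted-array k-mer index over a set of reference replicons."""

    k: int
    targets: list[SequenceRecord]
    sorted_codes: np.ndarray = field(repr=False)
    target_idx: np.ndarray = field(repr=False)
    offsets: np.ndarray = field(repr=False)

    def lookup(self, code: int, cap: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_codes, code, side="left")
        hi = np.searchsorted(self.sorted_codes, code, side="right")
        if hi - lo > cap:
            hi = lo + cap
        return self.target_idx[lo:hi], self.offsets[lo:hi]


def index_reference(refs: Sequence[SequenceRecord],
                    params: MapperParams = MapperParams()) -> SeedIndex:
    """Index every ACGT-only k-mer of every replicon.

    Replicons shorter than ``k`` are skipped with a warning.
    """
    if not refs:
        raise ValueError("cannot index an empty reference set")
    codes_all, tidx_all, off_all = [], [], []
    kept: list[SequenceRecord] = []
    for i, ref in enumerate(refs):
        if ref.length < params.k:
            logger.warning("replicon %s shorter than k=%d; skipped",
                           ref.id, params.k)
            kept.append(ref)  # keep identity so indices stay aligned
            continue
        codes, valid = _encode_kmers(ref.seq, params.k)
        pos = np.nonzero(valid)[0]
        codes_all.append(codes[pos])
        tidx_all.append(np.full(len(pos), i, dtype=np.int32))
        off_all.append(pos.astype(np.int64))
        kept.append(ref)
    if codes_all:
        codes = np.concatenate(codes_all)
        tidx = np.concatenate(tidx_all)
        offs = np.concatenate(off_all)
        order = np.argsort(codes, kind="stable")
        codes, tidx, offs = codes[order], tidx[order], offs[order]
    else:
        codes = np.empty(0, dtype=np.uint64)
        tidx = np.empty(0, dtype=np.int32)
        offs = np.empty(0, dtype=np.int64)
    return SeedIndex(k=params.k, targets=list(refs), sorted_codes=codes,
                     target_idx=tidx, offsets=offs)


def _collect_anchors(qseq: str, idx: SeedIndex,
                     params: MapperParams) -> dict[int, list[tuple[int, int]]]:
    """Anchors (query_pos, target_pos) per target index for one strand."""
    codes, valid = _encode_kmers(qseq, idx.k)
    n = len(codes)
    if n == 0 or idx.sorted_codes.size == 0:
        return {}
    stride = params.seed_stride if n > 4 * params.seed_stride else 1
    sel = np.arange(0, n, stride)
    sel = sel[valid[sel]]
    if sel.size == 0:
        return {}
    lo = np.searchsorted(idx.sorted_codes, codes[sel], side="left")
    hi = np.searchsorted(idx.sorted_codes, codes[sel], side="right")
    anchors: dict[int, list[tuple[int, int]]] = {}
    cap = params.max_hits_per_seed
    tidx, offs = idx.target_idx, idx.offsets
    for qpos, l, h in zip(sel.tolist(), lo.tolist(), hi.tolist()):
        if h - l > cap:
            h = l + cap
        for j in range(l, h):
            anchors.setdefault(int(tidx[j]), []).append((qpos, int(offs[j])))
    return anchors


def _chain_anchors(anchors: list[tuple[int, int]],
                   params: MapperParams) -> list[list[tuple[int, int]]]:
    """Greedy co-linear chaining of (q, t) anchors sorted by query position."""
    anchors = sorted(anchors)
    chains: list[list[tuple[int, int]]] = []
    max_step = params.max_seed_gap + params.k
    for q, t in anchors:
        best = None
        best_dd = None
        for chain in reversed(chains[-25:]):
            q0, t0 = chain[-1]
            if q <= q0 or t <= t0:
                continue
            if q - q0 > max_step or t - t0 > max_step:
                continue
            dd = abs((t - q) - (t0 - q0))
            if dd > params.max_seed_gap:
                continue
            if best_dd is None or dd < best_dd:
                best, best_dd = chain, dd
        if best is not None:
            best.append((q, t))
        else:
            chains.append([(q, t)])
    return [c for c in chains if len(c) >= params.min_chain_seeds]


def _xdrop_extend(qseq: str, tseq: str, q: int, t: int, direction: int,
                  params: MapperParams) -> int:
    """X-drop ungapped extension; returns number of bases to extend.

    ``direction`` +1 extends right starting at (q, t); -1 extends left
    starting just before (q, t).
    """
    score = best = 0
    best_ext = 0
    ext = 0
    qlen, tlen = len(qseq), len(tseq)
    while True:
        if direction > 0:
            qi, ti = q + ext, t + ext
            if qi >= qlen or ti >= tlen:
                break
        else:
            qi, ti = q - 1 - ext, t - 1 - ext
            if qi < 0 or ti < 0:
                break
        score += (params.match_score if qseq[qi] == tseq[ti]
                  else params.mismatch_score)
        ext += 1
        if score > best:
            best, best_ext = score, ext
        elif best - score >= params.xdrop:
            break
    return best_ext


def _align_span(qseq: str, tseq: str, qs: int, qe: int, ts: int, te: int):
    """Edit-distance global alignment of the spans; returns parsed CIGAR."""
    res = edlib.align(qseq[qs:qe], tseq[ts:te], mode="NW", task="path")
    return parse_cigar(res["cigar"])


def _records_for_strand(query: SequenceRecord, aln_seq: str, strand: str,
                        idx: SeedIndex,
                        params: MapperParams) -> list[AlignmentRecord]:
    recs: list[AlignmentRecord] = []
    qlen = query.length
    for ti, anchor_list in _collect_anchors(aln_seq, idx, params).items():
        target = idx.targets[ti]
        for chain in _chain_anchors(anchor_list, params):
            qs, ts = chain[0]
            qe, te = chain[-1][0] + params.k, chain[-1][1] + params.k
            left = _xdrop_extend(aln_seq, target.seq, qs, ts, -1, params)
            right = _xdrop_extend(aln_seq, target.seq, qe, te, +1, params)
            qs, ts = qs - left, ts - left
            qe, te = qe + right, te + right
            if qe - qs < params.min_block_len:
                continue
            cigar = _align_span(aln_seq, target.seq, qs, qe, ts, te)
            n_match = sum(o.run for o in cigar if o.op == "=")
            aln_cols = sum(o.run for o in cigar)
            nm = aln_cols - n_match
            if strand == "+":
                fqs, fqe = qs, qe
            else:  # coordinates back onto the forward query
                fqs, fqe = qlen - qe, qlen - qs
            recs.append(AlignmentRecord(
                query_id=query.id, query_len=qlen, query_start=fqs,
                query_end=fqe, strand=strand, target_id=target.id,
                target_len=target.length, target_start=ts, target_end=te,
                n_match=n_match, aln_cols=aln_cols, cigar=cigar, nm=nm))
    return recs


def _mark_primary(records: list[AlignmentRecord]) -> list[AlignmentRecord]:
    """Best-scoring record per query region is primary; records overlapping
    a better one by more than half their span become secondary."""
    records = sorted(records, key=lambda r: (-r.n_match, r.target_id,
                                             r.target_start, r.strand))
    taken: list[tuple[int, int]] = []
    for rec in records:
        span = rec.query_end - rec.query_start
        overlap = sum(max(0, min(rec.query_end, e) - max(rec.query_start, s))
                      for s, e in taken)
        if overlap * 2 > span:
            rec.is_primary = False
        else:
            rec.is_primary = True
            taken.append((rec.query_start, rec.query_end))
    records.sort(key=lambda r: (r.query_start, r.target_id, r.target_start))
    return records


def map_query(query: SequenceRecord, idx: SeedIndex,
              params: MapperParams = MapperParams()) -> list[AlignmentRecord]:
    """Map one query against the indexed replicons on both strands.

    Returns alignment records with extended CIGARs, best-per-region marked
    primary.  An empty list means no seed chain was found.
    """
    if query.length < idx.k:
        return []
    recs = _records_for_strand(query, query.seq, "+", idx, params)
    recs += _records_for_strand(query, reverse_complement(query.seq), "-",
                                idx, params)
    return _mark_primary(recs)


def map_reads(reads: Sequence[SequenceRecord],
              contigs: Sequence[SequenceRecord],
              params: MapperParams = MapperParams()) -> tuple[int, int]:
    """Count reads with at least one primary alignment to any contig.

    Each mate counts separately; ``total`` is the number of input reads.
    """
    total = len(reads)
    if not contigs or total == 0:
        return 0, total
    read_params = MapperParams(
        k=min(params.k, 13), seed_stride=params.seed_stride,
        min_chain_seeds=2, max_seed_gap=params.max_seed_gap,
        min_block_len=min(params.min_block_len, 50),
        match_score=params.match_score, mismatch_score=params.mismatch_score,
        xdrop=params.xdrop, max_hits_per_seed=params.max_hits_per_seed)
    idx = index_reference(contigs, read_params)
    mapped = 0
    for read in reads:
        hits = map_query(read, idx, read_params)
        if any(h.is_primary for h in hits):
            mapped += 1
    return mapped, total
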