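"""Per-replicon metrics: Pls, LSA, breadth, COMPASS, mismatches, GC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmqc.io import AlignmentRecord, SequenceRecord, parse_cigar
from asmqc.mapper import index_reference, map_query
from asmqc.misassembly import blocks_from_alignments
from asmqc.reference import (PLS_CAP, breadth_of_coverage, compass,
                             gc_content, lsa, mismatch_count,
                             per_reference_report, phred_like)

from conftest import mk_block, random_seq


def covered_fraction_oracle(intervals, length):
    """Per-base boolean-array oracle for breadth/coverage."""
    arr = np.zeros(length, dtype=bool)
    for s, e in intervals:
        arr[s:e] = True
    return arr.sum() / length


class TestPhredLike:
    def test_perfect_identity_scores_cap(self):
        assert phred_like(0.0) == 60.0

    def test_ten_percent_error_scores_10(self):
        assert phred_like(0.1) == pytest.approx(10.0)

    def test_total_error_scores_0(self):
        assert phred_like(1.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_domain_enforced(self, bad):
        with pytest.raises(ValueError):
            phred_like(bad)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    def test_monotone_nonincreasing_with_closed_form(self, e1, e2):
        lo, hi = sorted((e1, e2))
        assert phred_like(lo) >= phred_like(hi)
        # the closed form holds on (0, 1]; only E = 0 takes the 60 branch
        assert phred_like(hi) == pytest.approx(-10 * math.log10(hi))
        assert phred_like(0.0) == PLS_CAP


class TestBreadthAndLsa:
    def test_overlapping_intervals(self):
        blocks = [mk_block(ts=0, te=50), mk_block(ts=25, te=75)]
        assert breadth_of_coverage(blocks, 100) == pytest.approx(0.75)

    def test_no_blocks(self):
        assert breadth_of_coverage([], 100) == 0.0
        assert lsa([], 100) == 0.0

    def test_full_single_block(self):
        assert breadth_of_coverage([mk_block(ts=0, te=100)], 100) == 1.0
        assert lsa([mk_block(ts=0, te=100)], 100) == 1.0

    def test_lsa_takes_longest(self):
        blocks = [mk_block(ts=0, te=30), mk_block(ts=40, te=100)]
        assert lsa(blocks, 100) == pytest.approx(0.6)

    def test_zero_length_replicon_rejected(self):
        with pytest.raises(ValueError):
            breadth_of_coverage([], 0)
        with pytest.raises(ValueError):
            lsa([], 0)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 990), st.integers(1, 200)),
                    max_size=15))
    def test_breadth_matches_boolean_oracle(self, raw):
        length = 1000
        ivals = [(s, min(s + w, length)) for s, w in raw]
        blocks = [mk_block(qs=0, qe=e - s, ts=s, te=e) for s, e in ivals]
        assert breadth_of_coverage(blocks, length) == pytest.approx(
            covered_fraction_oracle(ivals, length))


class TestMismatchCount:
    def test_perfect_cigar(self):
        b = mk_block(n_match=100, aln_cols=100)
        b = b.__class__(**{**b.__dict__, "cigar":
                           tuple(parse_cigar("100="))})
        assert mismatch_count([b]) == 0

    def test_single_substitution(self):
        b = mk_block(n_match=99, aln_cols=100)
        b = b.__class__(**{**b.__dict__, "cigar":
                           tuple(parse_cigar("50=1X49="))})
        assert mismatch_count([b]) == 1

    def test_nm_fallback_subtracts_indel_bases(self):
        # NM=3 with one inserted base: 2 substitutions
        rec = AlignmentRecord("c1", 100, 0, 21, "+", "r1", 100, 0, 20,
                              18, 21, cigar=parse_cigar("10M1I10M"), nm=3)
        blocks = blocks_from_alignments([rec])
        assert mismatch_count(blocks, [rec]) == 2

    def test_unknowable_reported_missing_not_zero(self):
        rec = AlignmentRecord("c1", 100, 0, 20, "+", "r1", 100, 0, 20,
                              18, 20, cigar=None, nm=None)
        blocks = blocks_from_alignments([rec])
        assert mismatch_count(blocks, [rec]) is None


class TestCompass:
    def test_perfect_single_contig(self):
        blocks = [mk_block(qs=0, qe=100, ts=0, te=100)]
        m = compass(blocks, 100, 100)
        assert (m.coverage, m.validity, m.multiplicity, m.parsimony) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_duplicated_assembly_has_multiplicity_2(self):
        blocks = [mk_block(contig="c1", qs=0, qe=100, ts=0, te=100),
                  mk_block(contig="c2", qs=0, qe=100, ts=0, te=100)]
        m = compass(blocks, 100, 200)
        assert m.coverage == 1.0
        assert m.multiplicity == pytest.approx(2.0)
        assert m.validity == pytest.approx(1.0)
        assert m.parsimony == pytest.approx(2.0)

    def test_no_alignments_all_zero(self):
        m = compass([], 100, 0)
        assert (m.coverage, m.validity, m.multiplicity, m.parsimony) == \
            (0.0, 0.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 100)),
                    min_size=1, max_size=10))
    def test_coverage_matches_boolean_oracle(self, raw):
        length = 1000
        ivals = [(s, s + w) for s, w in raw]
        blocks = [mk_block(qs=0, qe=e - s, ts=s, te=e) for s, e in ivals]
        m = compass(blocks, length, sum(e - s for s, e in ivals))
        assert m.coverage == pytest.approx(
            covered_fraction_oracle(ivals, length))


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5),
        ("GGCC", 1.0),
        ("ATGN", 1 / 3),  # N excluded from the denominator
    ])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")


class TestPerReferenceReport:
    def test_perfect_single_contig_assembly(self, rng):
        ref = SequenceRecord("rep1", random_seq(rng, 5000))
        contig = SequenceRecord("c1", ref.seq)
        idx = index_reference([ref])
        alignments = map_query(contig, idx)
        rep = per_reference_report(ref, [contig], alignments)
        assert rep.breadth == 1.0
        assert rep.snps == 0
        assert rep.gaps == []
        assert rep.misassembly_calls == []
        (summary,) = rep.contig_summaries
        assert summary.pls == 60.0
        assert rep.compass.coverage == 1.0

    def test_unaligned_replicon_flagged(self, rng):
        ref_a = SequenceRecord("A", random_seq(rng, 3000))
        ref_b = SequenceRecord("B", random_seq(rng, 3000))
        contig = SequenceRecord("c1", ref_a.seq[:2000])
        idx = index_reference([ref_a, ref_b])
        alignments = map_query(contig, idx)
        rep_b = per_reference_report(ref_b, [contig], alignments)
        assert rep_b.no_alignment
        assert rep_b.breadth == 0.0
        assert len(rep_b.gaps) == 1

    def test_planted_substitution_rate_sets_pls(self, rng):
        # identity ~ 0.99 at a planted 1% substitution rate -> Pls ~ 20
        ref = SequenceRecord("rep1", random_seq(rng, 20_000))
        qseq = list(ref.seq)
        hits = rng.choice(20_000, size=200, replace=False)
        for pos in hits:
            qseq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[qseq[pos]]
        contig = SequenceRecord("c1", "".join(qseq))
        idx = index_reference([ref])
        rep = per_reference_report(ref, [contig], map_query(contig, idx))
        (summary,) = rep.contig_summaries
        assert summary.identity == pytest.approx(0.99, abs=0.001)
        assert summary.pls == pytest.approx(20.0, abs=0.5)
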