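"""Block building and the misassembly classifier rule table."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from asmqc.io import AlignmentRecord, parse_cigar
from asmqc.misassembly import (AlignmentBlock, ClassifierThresholds,
                               blocks_from_alignments, classify, summarize)

from conftest import mk_block

TH = ClassifierThresholds()


class TestBlocksFromAlignments:
    def test_clean_record_is_one_block(self):
        rec = AlignmentRecord("c", 1000, 0, 1000, "+", "r", 2000, 0, 1000,
                              1000, 1000, cigar=parse_cigar("1000="))
        (b,) = blocks_from_alignments([rec])
        assert (b.q_start, b.q_end, b.t_start, b.t_end) == (0, 1000, 0, 1000)

    def test_large_deletion_splits_with_target_gap(self):
        rec = AlignmentRecord("c", 1000, 0, 1000, "+", "r", 2000, 0, 1060,
                              1000, 1060, cigar=parse_cigar("500=60D500="))
        b1, b2 = blocks_from_alignments([rec])
        assert (b1.q_end, b2.q_start) == (500, 500)
        assert b2.t_start - b1.t_end == 60

    def test_large_insertion_splits_with_query_gap(self):
        rec = AlignmentRecord("c", 1060, 0, 1060, "+", "r", 2000, 0, 1000,
                              1000, 1060, cigar=parse_cigar("500=60I500="))
        b1, b2 = blocks_from_alignments([rec])
        assert b2.q_start - b1.q_end == 60
        assert (b1.t_end, b2.t_start) == (500, 500)

    def test_small_indel_not_split(self):
        rec = AlignmentRecord("c", 1000, 0, 1000, "+", "r", 2000, 0, 1010,
                              1000, 1010, cigar=parse_cigar("500=10D500="))
        assert len(blocks_from_alignments([rec])) == 1

    def test_two_records_two_blocks_sorted(self):
        r1 = AlignmentRecord("c", 1000, 500, 1000, "+", "r", 2000, 0, 500,
                             500, 500, cigar=parse_cigar("500="))
        r2 = AlignmentRecord("c", 1000, 0, 500, "+", "r", 2000, 1000, 1500,
                             500, 500, cigar=parse_cigar("500="))
        b1, b2 = blocks_from_alignments([r1, r2])
        assert b1.q_start == 0 and b2.q_start == 500

    def test_secondary_records_excluded(self):
        rec = AlignmentRecord("c", 1000, 0, 1000, "+", "r", 2000, 0, 1000,
                              1000, 1000, cigar=parse_cigar("1000="),
                              is_primary=False)
        assert blocks_from_alignments([rec]) == []

    def test_minus_strand_coordinates_forward(self):
        # rc(query)[0:1000] aligns t [0:1060] with a 60 bp deletion split;
        # forward-contig coordinates must mirror accordingly
        rec = AlignmentRecord("c", 1000, 0, 1000, "-", "r", 2000, 0, 1060,
                              1000, 1060, cigar=parse_cigar("500=60D500="))
        b1, b2 = blocks_from_alignments([rec])
        assert (b1.q_start, b1.q_end) == (0, 500)
        assert (b2.q_start, b2.q_end) == (500, 1000)
        # first block along the contig corresponds to the later target span
        assert b1.t_start == 560 and b2.t_start == 0


class TestClassifier:
    def test_single_block_clean(self):
        call = classify([mk_block()], TH)
        assert call.categories == frozenset()
        assert call.events == []

    def test_chimera_is_exclusive(self):
        blocks = [mk_block(qs=0, qe=5000, rep="A", ts=0, te=5000),
                  mk_block(qs=5000, qe=10_000, rep="B", ts=0, te=5000,
                           strand="-")]
        call = classify(blocks, TH)
        assert call.categories == frozenset({"chimera"})
        assert len(call.events) == 1

    def test_inversion_on_opposite_strands(self):
        blocks = [mk_block(qs=0, qe=500, ts=0, te=500, strand="+"),
                  mk_block(qs=500, qe=1000, ts=500, te=1000, strand="-")]
        assert classify(blocks, TH).categories == frozenset({"inversion"})

    def test_translocation_on_distal_target_gap(self):
        # contiguous on the contig, 5,000 bp apart on the replicon
        blocks = [mk_block(qs=0, qe=500, ts=0, te=500),
                  mk_block(qs=500, qe=1000, ts=5500, te=6000)]
        assert classify(blocks, TH).categories == frozenset({"translocation"})

    def test_deletion_below_translocation_threshold(self):
        blocks = [mk_block(qs=0, qe=500, ts=0, te=500),
                  mk_block(qs=500, qe=1000, ts=600, te=1100)]
        assert classify(blocks, TH).categories == frozenset({"deletion"})

    def test_insertion_on_contig_gap(self):
        blocks = [mk_block(qs=0, qe=500, ts=0, te=500),
                  mk_block(qs=600, qe=1100, ts=500, te=1000)]
        assert classify(blocks, TH).categories == frozenset({"insertion"})

    def test_duplication_on_target_overlap(self):
        blocks = [mk_block(qs=0, qe=600, ts=0, te=600),
                  mk_block(qs=600, qe=1200, ts=500, te=1100)]
        assert classify(blocks, TH).categories == frozenset({"duplication"})

    def test_rearrangement_on_order_inversion(self):
        blocks = [mk_block(qs=0, qe=500, ts=2000, te=2500),
                  mk_block(qs=500, qe=1000, ts=0, te=500)]
        assert classify(blocks, TH).categories == frozenset({"rearrangement"})

    def test_inconsistent_fallback(self):
        # two blocks, every pair quantity below threshold
        blocks = [mk_block(qs=0, qe=500, ts=0, te=500),
                  mk_block(qs=510, qe=1000, ts=510, te=1000)]
        assert classify(blocks, TH).categories == frozenset({"inconsistent"})

    def test_unsorted_blocks_rejected(self):
        blocks = [mk_block(qs=500, qe=1000), mk_block(qs=0, qe=400)]
        with pytest.raises(ValueError, match="sorted"):
            classify(blocks, TH)

    def test_combination_insertion_plus_duplication(self):
        blocks = [mk_block(qs=0, qe=500, ts=0, te=500),
                  mk_block(qs=600, qe=1100, ts=400, te=900),
                  mk_block(qs=1100, qe=1600, ts=2500, te=3000)]
        call = classify(blocks, TH)
        assert {"insertion", "duplication", "translocation"} <= call.categories
        assert len(call.events) >= 3

    def test_reverse_complement_invariance(self):
        # flipping the whole contig flips block order and strands jointly
        cases = [
            [mk_block(qs=0, qe=500, ts=0, te=500),
             mk_block(qs=500, qe=1000, ts=5500, te=6000)],
            [mk_block(qs=0, qe=500, ts=2000, te=2500),
             mk_block(qs=500, qe=1000, ts=0, te=500)],
            [mk_block(qs=0, qe=600, ts=0, te=600),
             mk_block(qs=600, qe=1200, ts=500, te=1100)],
        ]
        L = 2000
        for blocks in cases:
            flipped = sorted(
                (dataclasses.replace(
                    b, q_start=L - b.q_end, q_end=L - b.q_start,
                    strand="-" if b.strand == "+" else "+")
                 for b in blocks), key=lambda b: b.q_start)
            assert classify(blocks, TH).categories == \
                classify(flipped, TH).categories


@st.composite
def block_sets(draw):
    n = draw(st.integers(1, 6))
    blocks = []
    q = 0
    for _ in range(n):
        q += draw(st.integers(0, 200))
        span = draw(st.integers(10, 800))
        ts = draw(st.integers(0, 8000))
        blocks.append(mk_block(
            qs=q, qe=q + span,
            strand=draw(st.sampled_from("+-")),
            rep=draw(st.sampled_from(["A", "B"])),
            ts=ts, te=ts + span))
        q += span
    return blocks


class TestClassifierInvariants:
    @settings(derandomize=True, max_examples=300)
    @given(block_sets())
    def test_chimera_exclusivity_never_violated(self, blocks):
        call = classify(blocks, TH)
        if "chimera" in call.categories:
            assert call.categories == frozenset({"chimera"})
        if not call.categories:
            assert call.events == []
        assert call.categories == frozenset(e.category for e in call.events)

    @settings(derandomize=True, max_examples=100)
    @given(block_sets())
    def test_multi_block_always_classified(self, blocks):
        call = classify(blocks, TH)
        if len(blocks) >= 2:
            assert call.categories  # at worst "inconsistent"
        # at most k-1 pair events plus one chimera
        assert len(call.events) <= 5 * (len(blocks) - 1) + 1 if blocks else 1


class TestSummarize:
    def test_empty(self):
        assert summarize([]) == (0, 0, {})

    def test_counts(self):
        chim = classify([mk_block(qs=0, qe=500, rep="A"),
                         mk_block(qs=500, qe=1000, rep="B", ts=0, te=500)],
                        TH)
        inv = classify([mk_block(contig="c2", qs=0, qe=500, strand="+"),
                        mk_block(contig="c2", qs=500, qe=1000, ts=500,
                                 te=1000, strand="-")], TH)
        clean = classify([mk_block(contig="c3")], TH)
        n_contigs, n_events, per_cat = summarize([chim, inv, clean])
        assert n_contigs == 2
        assert n_events == 2
        assert per_cat == {"chimera": 1, "inversion": 1}

    def test_one_contig_two_event_categories(self):
        call = classify([mk_block(qs=0, qe=500, ts=0, te=500),
                         mk_block(qs=600, qe=1100, ts=500, te=1000),
                         mk_block(qs=1100, qe=1700, ts=900, te=1500)], TH)
        n_contigs, n_events, per_cat = summarize([call])
        assert n_contigs == 1
        assert n_events == 2
        assert per_cat == {"insertion": 1, "duplication": 1}
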