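"""Variant normalization, event merging, classification and decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radmut.events import (
    Category,
    build_events,
    classify_event,
    describe_complex,
    merge_into_events,
)
from radmut.genome import ReferenceGenome
from radmut.variants import (
    VariantClass,
    apply_variants,
    normalize_variant,
)

from conftest import deletion, insertion, make_call, sbs
from oracles import (
    leftmost_deletion_placement,
    leftmost_insertion_placement,
    union_find_events,
)


class TestNormalization:
    def test_homopolymer_deletion_left_aligned(self, toy_ref):
        # chr1[28..32] = "CAAAT": deleting the 3rd A equals deleting the 1st
        call = deletion(31, "A")
        norm = normalize_variant(call, toy_ref)
        seq = toy_ref.sequences["chr1"]
        assert norm.pos == leftmost_deletion_placement(seq, 31, 31)
        assert norm.pos == 29

    def test_substitution_unchanged(self, toy_ref):
        call = sbs(9, "G", "T")
        assert normalize_variant(call, toy_ref) is call

    def test_insertion_left_aligned_against_oracle(self, toy_ref):
        # chr1[36..40] = "TATCC": inserting "AT" after position 38 ("A")
        call = insertion(38, "AT")
        norm = normalize_variant(call, toy_ref)
        seq = toy_ref.sequences["chr1"]
        pos_oracle, seq_oracle = leftmost_insertion_placement(seq, 38, "AT")
        assert (norm.pos, norm.alt_allele) == (pos_oracle, seq_oracle)

    def test_ref_mismatch_raises(self, toy_ref):
        with pytest.raises(ValueError, match="mismatch"):
            normalize_variant(deletion(9, "T"), toy_ref)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_deletions_match_placement_oracle(self, data):
        seq = data.draw(
            st.text(alphabet="ACGT", min_size=10, max_size=40), label="seq"
        )
        start = data.draw(st.integers(2, len(seq) - 3), label="start")
        length = data.draw(st.integers(1, len(seq) - start - 1), label="len")
        ref = ReferenceGenome({"c": seq})
        call = deletion(start, seq[start - 1 : start + length - 1], chrom="c")
        norm = normalize_variant(call, ref)
        assert norm.pos == leftmost_deletion_placement(
            seq, start, start + length - 1
        )


class TestMerging:
    def test_linked_within_window(self, toy_ref):
        events = merge_into_events([sbs(9, "G", "T"), sbs(14, "T", "A")])
        assert len(events) == 1
        assert len(events[0].members) == 2

    def test_exactly_ten_intervening_bases_not_linked(self):
        events = merge_into_events(
            [sbs(100, "A", "G"), sbs(111, "A", "G")]
        )
        assert len(events) == 2

    def test_transitive_closure_chains(self):
        events = merge_into_events(
            [sbs(100, "A", "G"), sbs(108, "A", "G"), sbs(116, "A", "G")]
        )
        assert len(events) == 1
        assert len(events[0].members) == 3

    def test_sv_never_merges_with_small_variants(self):
        inv = make_call(
            105, "", "", "inversion", end=2000, zygosity="heterozygous"
        )
        events = merge_into_events([sbs(100, "A", "G"), inv])
        assert len(events) == 2

    def test_order_independent_and_idempotent(self):
        calls = [sbs(p, "A", "G") for p in (300, 100, 105, 290, 150)]
        a = merge_into_events(calls)
        b = merge_into_events(list(reversed(calls)))
        key = lambda evs: [(e.start, e.end, len(e.members)) for e in evs]
        assert key(a) == key(b)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        positions=st.lists(
            st.integers(1, 300), min_size=1, max_size=12, unique=True
        ),
        window=st.integers(1, 15),
    )
    def test_components_equal_union_find_oracle(self, positions, window):
        calls = [sbs(p, "A", "G") for p in positions]
        events = merge_into_events(calls, window_bp=window)
        got = sorted(
            sorted(m.pos for m in e.members) for e in events
        )
        spans = [(p, p) for p in sorted(positions)]
        expected = sorted(
            sorted(spans[i][0] for i in grp)
            for grp in union_find_events(spans, window)
        )
        assert got == expected


class TestClassification:
    @pytest.mark.parametrize(
        "call,category",
        [
            (sbs(9, "G", "T"), Category.SBS),
            (deletion(20, "A"), Category.DEL1),
            (deletion(20, "AATTCCGGCAAATGG"), Category.DEL_GE2),
            (insertion(15, "C"), Category.INS1),
            (insertion(15, "CTT"), Category.INS_GE2),
            (
                make_call(5, "", "", "inversion", end=500, zygosity="heterozygous"),
                Category.SV,
            ),
        ],
    )
    def test_single_member_categories(self, call, category):
        (event,) = merge_into_events([call])
        assert classify_event(event).category is category

    def test_sbs_plus_deletion_nearby_is_complex(self):
        (event,) = merge_into_events([sbs(100, "A", "G"), deletion(106, "AAT")])
        assert classify_event(event).category is Category.COMPLEX

    def test_mixed_zygosity_flagged_with_majority_label(self):
        calls = [
            sbs(100, "A", "G", zygosity="homozygous"),
            sbs(104, "A", "G", zygosity="homozygous"),
            sbs(108, "A", "G", zygosity="heterozygous"),
        ]
        (event,) = merge_into_events(calls)
        assert event.mixed_zygosity
        assert event.zygosity == "homozygous"


class TestComplexDecomposition:
    def test_two_sbs_separated_by_two_matching_bases(self, toy_ref):
        # chr1: pos 9 G, 10 G, 11 A, 12 C -> SBSs at 9 and 12, spacer of 2
        calls = [sbs(9, "G", "T"), sbs(12, "C", "A")]
        (event,) = merge_into_events(calls)
        classify_event(event)
        blocks = describe_complex(event, toy_ref)
        assert [b.kind for b in blocks] == ["substitution-run"] * 2

    def test_single_matching_base_absorbed(self, toy_ref):
        # SBSs at 9 and 11 leave a single matching base at 10
        calls = [sbs(9, "G", "T"), sbs(11, "A", "C")]
        (event,) = merge_into_events(calls)
        blocks = describe_complex(event, toy_ref)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (9, 11)
        assert blocks[0].ref_seq == "GGA"
        assert blocks[0].alt_seq == "TGC"

    def test_single_member_block_equals_variant(self, toy_ref):
        calls = [sbs(9, "G", "T"), sbs(25, "C", "G")]  # far apart: not complex
        (event,) = merge_into_events([calls[0]])
        blocks = describe_complex(event, toy_ref)
        assert len(blocks) == 1
        assert (blocks[0].ref_seq, blocks[0].alt_seq) == ("G", "T")

    def test_roundtrip_members_reproduce_composition(self, toy_ref):
        calls = [sbs(9, "G", "T"), deletion(13, "GT"), insertion(19, "AA")]
        (event,) = merge_into_events(calls)
        blocks = describe_complex(event, toy_ref)
        derived = apply_variants(toy_ref, "chr1", list(event.members), 1, 60)
        # splicing the blocks into the reference must agree
        out, cursor = [], 1
        for b in blocks:
            if b.end >= b.start:  # replacement / deletion block
                out.append(toy_ref.fetch("chr1", cursor, b.start - 1))
                out.append(b.alt_seq)
                cursor = b.end + 1
            else:  # insertion block between b.end and b.start
                out.append(toy_ref.fetch("chr1", cursor, b.end))
                out.append(b.alt_seq)
                cursor = b.start
        out.append(toy_ref.fetch("chr1", cursor, 60))
        assert "".join(out) == derived


class TestEndToEndCategories:
    def test_spiked_categories_recovered_exactly(self):
        """Isolated spike-ins of every category classify back to it."""
        from radmut.simulate import generate_reference, spike_mutations, wt_profile

        ref = generate_reference(200_000, seed=11)
        truth = spike_mutations(ref, wt_profile(), 2, seed=12)
        for sample, events in truth.plants.items():
            rebuilt = build_events(
                [m for e in events for m in e.members], ref
            )
            assert [
                (e.start, e.category) for e in sorted(events, key=lambda e: (e.chrom, e.start))
            ] == [
                (e.start, e.category) for e in rebuilt
            ]
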