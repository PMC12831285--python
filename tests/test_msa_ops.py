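"""Alignment parsing and the MSA steering operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldguide.feature_store import GAP_INDEX, QueryFeatures
from foldguide.fixtures import make_toy_msa
from foldguide.msa_ops import (RegionSelection, add_fragment_library,
                               mask_region, merge, parse_alignment,
                               reduce_depth, write_a3m)

from oracles import a3m_row_reference


@pytest.fixture
def block50():
    return make_toy_msa("ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKL",
                        n_rows=50, conservation=0.7, seed=5)


class TestParseAlignment:
    def test_a3m_insertion_semantics(self, tmp_path):
        # lowercase insertions accumulate into the next match column
        p = tmp_path / "t.a3m"
        p.write_text(">query\nACDEF\n>row1\nAC-dEF\n")
        block = parse_alignment(p, "a3m", "ACDEF")
        row, dels = a3m_row_reference("ACDEF", "AC-dEF")
        assert block.rows[1].tolist() == row == [0, 4, 21, 6, 13]
        assert block.deletion_counts[1].tolist() == dels == [0, 0, 0, 1, 0]

    def test_query_only_file_matches_empty_container(self, tmp_path):
        from foldguide.feature_store import empty_features
        p = tmp_path / "q.a3m"
        p.write_text(">query\nACDEF\n")
        block = parse_alignment(p, "a3m", "ACDEF")
        fs = empty_features("ACDEF")
        assert block.depth == 1
        assert np.array_equal(block.rows, fs.msa.rows)

    def test_mismatched_match_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.a3m"
        p.write_text(">query\nACDEF\n>row1\nAC-EF-\n")
        with pytest.raises(ValueError, match="match columns"):
            parse_alignment(p, "a3m", "ACDEF")

    def test_aligned_fasta_and_stockholm(self, tmp_path):
        fasta = tmp_path / "aln.fasta"
        fasta.write_text(">query\nAC-DEF\n>row1\nACWD-F\n")
        block = parse_alignment(fasta, "fasta", "ACDEF")
        # the column where the query is gapped becomes an insertion of row1
        assert block.rows[1].tolist() == [0, 4, 3, 21, 13]
        assert block.deletion_counts[1].tolist() == [0, 0, 1, 0, 0]

        sto = tmp_path / "aln.sto"
        sto.write_text("# STOCKHOLM 1.0\nquery  ACDEF\nrow1   AC-EF\n//\n")
        block2 = parse_alignment(sto, "stockholm", "ACDEF")
        assert block2.rows[1].tolist() == [0, 4, 21, 6, 13]

    def test_roundtrip_through_a3m_writer(self, tmp_path, block50):
        from foldguide.feature_store import decode_sequence
        p = tmp_path / "out.a3m"
        write_a3m(block50, p)
        block2 = parse_alignment(p, "a3m", decode_sequence(block50.rows[0]))
        assert np.array_equal(block2.rows, block50.rows)


class TestReduceDepth:
    def test_top_is_prefix(self, block50):
        out = reduce_depth(block50, 30, "top")
        assert out.depth == 30
        assert np.array_equal(out.rows, block50.rows[:30])

    def test_n1_keeps_query_only(self, block50):
        out = reduce_depth(block50, 1, "top")
        assert out.depth == 1
        assert np.array_equal(out.rows[0], block50.rows[0])

    def test_n_exceeding_depth_is_identity(self, block50):
        out = reduce_depth(block50, 1000, "top")
        assert np.array_equal(out.rows, block50.rows)

    def test_diverse_is_seeded_and_keeps_query(self, block50):
        a = reduce_depth(block50, 10, "diverse", seed=3)
        b = reduce_depth(block50, 10, "diverse", seed=3)
        assert np.array_equal(a.rows, b.rows)
        assert np.array_equal(a.rows[0], block50.rows[0])
        assert a.depth == 10


class TestMaskRegion:
    def test_masks_19_columns_in_non_query_rows(self, block50):
        # e.g. silencing the loops behind an unwanted dimer interface
        region = RegionSelection([("*", 10, 28)])
        out = mask_region(block50, region)
        assert out.width == block50.width
        assert out.depth == block50.depth
        assert np.all(out.rows[1:, 9:28] == GAP_INDEX)
        assert np.all(out.deletion_counts[1:, 9:28] == 0)
        assert np.array_equal(out.rows[0], block50.rows[0])

    def test_idempotent(self, block50):
        region = RegionSelection([("*", 10, 28)])
        once = mask_region(block50, region)
        twice = mask_region(once, region)
        assert np.array_equal(once.rows, twice.rows)

    def test_disjoint_masks_commute(self, block50):
        r1 = RegionSelection([("*", 1, 5)])
        r2 = RegionSelection([("*", 20, 30)])
        ab = mask_region(mask_region(block50, r1), r2)
        ba = mask_region(mask_region(block50, r2), r1)
        assert np.array_equal(ab.rows, ba.rows)

    def test_mask_everything_keeps_depth(self, block50):
        out = mask_region(block50, RegionSelection([("*", 1, block50.width)]))
        assert out.depth == block50.depth
        assert np.all(out.rows[1:] == GAP_INDEX)

    def test_out_of_range_rejected(self, block50):
        with pytest.raises(ValueError, match="outside"):
            mask_region(block50, RegionSelection([("*", 1, 9999)]))


class TestMerge:
    def test_disjoint_chain_blocks_are_gap_padded(self):
        qa, qb = "ACDEFGHIKL", "MNPQRSTVWY"
        query = QueryFeatures.from_sequence(qa + qb)
        ba = make_toy_msa(qa, 5, 0.8, seed=1)
        bb = make_toy_msa(qb, 4, 0.8, seed=2)
        out = merge([(ba, RegionSelection([("*", 1, 10)])),
                     (bb, RegionSelection([("*", 11, 20)]))], query)
        assert out.width == 20
        assert out.depth == 1 + 4 + 3
        # rows from the first block are gap outside their region
        assert np.all(out.rows[1:5, 10:] == GAP_INDEX)
        assert np.all(out.rows[5:, :10] == GAP_INDEX)

    def test_self_merge_deduplicates(self):
        q = "ACDEFGHIKL"
        query = QueryFeatures.from_sequence(q)
        b = make_toy_msa(q, 6, 0.8, seed=3)
        out = merge([(b, None), (b, None)], query)
        assert out.depth == b.depth

    def test_width_conflict_rejected(self):
        query = QueryFeatures.from_sequence("ACDEFGHIKL")
        b = make_toy_msa("ACDEF", 3, 1.0, seed=0)
        with pytest.raises(ValueError, match="width"):
            merge([(b, None)], query)


class TestFragmentLibrary:
    def test_fragment_rows_cover_only_their_region(self):
        # a 15-residue interaction fragment placed on a 110-residue query
        q = "AEKLVDGSTR" * 11
        block = make_toy_msa(q, 3, 0.9, seed=0)
        frag = "CAEKLVDGSTRAEKC"
        out = add_fragment_library(
            block, [(frag, RegionSelection([("*", 20, 34)]))])
        assert out.depth == block.depth + 1
        new = out.rows[-1]
        assert int((new != GAP_INDEX).sum()) == 15
        assert np.all(new[19:34] != GAP_INDEX)

    def test_empty_library_is_identity(self):
        block = make_toy_msa("ACDEFGHIKL", 3, 0.9, seed=0)
        out = add_fragment_library(block, [])
        assert np.array_equal(out.rows, block.rows)

    def test_length_mismatch_and_illegal_fragment(self):
        block = make_toy_msa("ACDEFGHIKL", 2, 1.0, seed=0)
        with pytest.raises(ValueError, match="length"):
            add_fragment_library(block,
                                 [("AAA", RegionSelection([("*", 1, 5)]))])
        with pytest.raises(ValueError):
            add_fragment_library(block,
                                 [("AZDEF", RegionSelection([("*", 1, 5)]))])


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10**6), st.integers(1, 49), st.integers(1, 49))
def test_operations_preserve_width_and_query(seed, a, b):
    """Every MSA operation preserves the width and the query row exactly."""
    q = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIK"
    block = make_toy_msa(q, 12, 0.6, seed=seed)
    lo, hi = min(a, b), max(a, b)
    for op in (
        lambda m: mask_region(m, RegionSelection([("*", lo, hi)])),
        lambda m: reduce_depth(m, 5, "top"),
        lambda m: reduce_depth(m, 5, "diverse", seed=seed),
        lambda m: add_fragment_library(
            m, [("C" * (hi - lo + 1), RegionSelection([("*", lo, hi)]))]),
    ):
        out = op(block)
        assert out.width == block.width
        assert np.array_equal(out.rows[0], block.rows[0])
        assert np.all(out.deletion_counts[0] == 0)
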