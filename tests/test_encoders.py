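"""Encoder dimensionality, one-hot structure and cross-encoder consistency."""

import shutil

import numpy as np
import pytest

from conftest import random_pair
from featkit.core_io import BEScreenRecord, DatasetTable, PairedSiteRecord
from featkit.encoders import (
    EncoderSpec,
    GappedInputError,
    UnsupportedSymbolError,
    append_distance,
    compute_distance,
    decode_lep,
    encode_8xl,
    encode_bulges,
    encode_dataset,
    encode_kmer,
    encode_lep,
    encode_mm,
    encode_npm,
    encode_oh5c,
    encode_onehot,
    folding_energy,
    gc_content,
    melting_temperature,
    npm_feature_names,
)


def _pair(guide: str, target: str, count: float = 1.0) -> PairedSiteRecord:
    return PairedSiteRecord("g", guide, target, count)


SEQ23 = "ACGTACGTACGTACGTACGTAGG"


class TestDimensionality:
    """Feature counts derived from the aligned length (L=23 defaults)."""

    def test_dimension_table_at_length_23(self):
        pair = _pair(SEQ23, SEQ23)
        assert len(encode_npm(pair)) == 368
        assert len(encode_bulges(pair)) == 575
        assert len(encode_lep(pair)) == 23
        assert len(encode_mm(pair)) == 23
        assert len(encode_8xl(pair)) == 184
        assert len(encode_onehot(pair)) == 92
        assert len(encode_oh5c(pair)) == 115
        assert len(encode_kmer(SEQ23)) == 64
        assert len(encode_kmer(SEQ23, EncoderSpec("KMER", kmer_compact=True))) == 63

    def test_dimensions_scale_with_toy_length(self):
        pair = _pair("ACG", "ACT")
        assert len(encode_npm(pair)) == 48
        assert len(encode_lep(pair)) == 3
        assert len(encode_8xl(pair)) == 24


class TestNPM:
    def test_identity_pair_hits_diagonal_cells(self):
        vec = encode_npm(_pair(SEQ23, SEQ23))
        assert vec.sum() == 23
        names = npm_feature_names(23)
        hot = {names[i] for i in np.nonzero(vec)[0]}
        assert all(name[-2] == name[-1] for name in hot)

    def test_single_mismatch_construction(self):
        vec = encode_npm(_pair("ACG", "ACT"))
        names = npm_feature_names(3)
        hot = {names[i] for i in np.nonzero(vec)[0]}
        assert hot == {"pos1_AA", "pos2_CC", "pos3_GT"}

    def test_per_position_blocks_sum_to_one(self, rng):
        for _ in range(50):
            vec = encode_npm(_pair(*random_pair(rng)))
            assert np.array_equal(vec.reshape(23, 16).sum(axis=1), np.ones(23))

    def test_gapped_input_points_to_bulges(self):
        with pytest.raises(GappedInputError, match="BULGES"):
            encode_npm(_pair("A-G", "ATG"))

    def test_n_unsupported(self):
        with pytest.raises(UnsupportedSymbolError):
            encode_npm(_pair("ANG", "ACG"))


class TestBulges:
    def test_reduces_to_npm_when_ungapped(self, rng):
        pair = _pair(*random_pair(rng))
        npm = encode_npm(pair).reshape(23, 4, 4)
        bul = encode_bulges(pair).reshape(23, 5, 5)
        assert np.array_equal(bul[:, :4, :4], npm)
        assert bul[:, 4, :].sum() == 0 and bul[:, :, 4].sum() == 0

    def test_guide_gap_sets_gap_row(self):
        vec = encode_bulges(_pair("AC-", "ACG")).reshape(3, 5, 5)
        assert vec[2, 4, 2] == 1  # ('-', 'G') cell at position 3

    def test_gap_gap_cell_never_set(self, rng):
        # gap-vs-gap is structurally impossible; the cell stays zero
        for _ in range(100):
            guide, target = random_pair(rng, length=10)
            i = rng.integers(10)
            grid = encode_bulges(
                _pair(guide[:i] + "-" + guide[i:], target[:i] + "A" + target[i:])
            ).reshape(11, 5, 5)
            assert grid[:, 4, 4].sum() == 0


class TestLEP:
    def test_all_a_identity_is_zero_vector(self):
        assert np.array_equal(encode_lep(_pair("A" * 23, "A" * 23)), np.zeros(23))

    def test_tt_pair_maps_to_15(self):
        # lexicographic index of (T, T) among the 16 ordered pairs
        vec = encode_lep(_pair("AT", "AT"))
        assert vec[1] == 15.0

    def test_round_trip_reconstructs_both_sequences(self, rng):
        for _ in range(50):
            guide, target = random_pair(rng)
            assert decode_lep(encode_lep(_pair(guide, target))) == (guide, target)


class TestMMAndDistance:
    def test_identity_is_zero(self):
        assert encode_mm(_pair(SEQ23, SEQ23)).sum() == 0

    def test_single_mismatch(self):
        assert np.array_equal(encode_mm(_pair("ACG", "ACT")), [0, 0, 1])

    def test_mm_sum_equals_distance_brute_force(self, rng):
        for _ in range(1000):
            guide, target = random_pair(rng, length=int(rng.integers(4, 24)))
            pair = _pair(guide, target)
            brute = sum(g != t for g, t in zip(guide, target))
            assert encode_mm(pair).sum() == compute_distance(pair) == brute

    def test_gap_counts_as_one_edit(self):
        assert compute_distance(_pair("A-GT", "AAGT")) == 1


class TestOneHot:
    def test_pair_or_idempotent_on_identity(self):
        pair = _pair(SEQ23, SEQ23)
        single = BEScreenRecord("g", SEQ23, 0.0)
        assert np.array_equal(encode_onehot(pair), encode_onehot(single))

    def test_or_sets_both_bases_at_mismatch(self):
        vec = encode_onehot(_pair("AAAAA", "AAAAG")).reshape(5, 4)
        assert np.array_equal(vec[4], [1, 0, 1, 0])  # A and G both set

    def test_blocksum2_positions_equal_distance(self, rng):
        for _ in range(200):
            pair = _pair(*random_pair(rng))
            blocks = encode_onehot(pair).reshape(23, 4).sum(axis=1)
            assert (blocks == 2).sum() == compute_distance(pair)
            assert set(np.unique(blocks)) <= {1.0, 2.0}

    def test_mm_oh_npm_mutual_consistency(self, rng):
        # positions flagged by MM == OH block-sum-2 == off-diagonal NPM cells
        for _ in range(300):
            pair = _pair(*random_pair(rng))
            mm = encode_mm(pair).astype(bool)
            oh = encode_onehot(pair).reshape(23, 4).sum(axis=1) == 2
            npm = encode_npm(pair).reshape(23, 4, 4)
            off_diag = np.array(
                [npm[p].sum() - np.trace(npm[p]) == 1 for p in range(23)]
            )
            assert np.array_equal(mm, oh) and np.array_equal(mm, off_diag)


class TestOH5C:
    def test_gap_free_single_reduces_to_onehot(self):
        single = BEScreenRecord("g", SEQ23, 0.0)
        five = encode_oh5c(single).reshape(23, 5)
        assert five[:, 4].sum() == 0
        assert np.array_equal(five[:, :4].ravel(), encode_onehot(single))

    def test_n_fires_x_channel(self):
        vec = encode_oh5c(_pair("ANG", "ACG")).reshape(3, 5)
        assert vec[1, 4] == 1

    def test_pair_block_sums_in_one_two(self, rng):
        pair = _pair(*random_pair(rng))
        blocks = encode_oh5c(pair).reshape(23, 5).sum(axis=1)
        assert set(np.unique(blocks)) <= {1.0, 2.0}


class TestKmer:
    def test_homopolymer_sliding_window(self):
        vec = encode_kmer("AAAAA")
        assert vec[0] == 3 and vec.sum() == 3

    def test_acgt_counts(self):
        spec = EncoderSpec("KMER")
        vec = encode_kmer("ACGT", spec)
        from featkit.encoders import kmer_vocabulary

        vocab = kmer_vocabulary(3)
        assert vec[vocab.index("ACG")] == 1 and vec[vocab.index("CGT")] == 1
        assert vec.sum() == 2

    def test_compact_drops_ttt(self):
        from featkit.encoders import kmer_vocabulary

        vocab = kmer_vocabulary(3, compact=True)
        assert len(vocab) == 63 and "TTT" not in vocab

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="< k"):
            encode_kmer("AC")


class TestEncodeDataset:
    def test_alignment_encodings_reject_be(self, toy_be_table):
        with pytest.raises(ValueError, match="alignment-based"):
            encode_dataset(toy_be_table, EncoderSpec("NPM"))

    def test_kmer_encodes_target_for_ko_and_guide_for_be(self, toy_be_table):
        ko = DatasetTable(
            "KO", [PairedSiteRecord("g", "AAACA", "AAAAA", 1.0)]
        )
        vec = encode_dataset(ko, EncoderSpec("KMER")).values[0]
        assert vec[0] == 3  # off-target AAAAA, not the guide
        be = encode_dataset(toy_be_table, EncoderSpec("KMER"))
        assert be.n_samples == len(toy_be_table)

    def test_with_distance_appends_last_column(self, toy_ko_table):
        matrix = encode_dataset(toy_ko_table, EncoderSpec("NPM", with_distance=True))
        assert matrix.n_features == 369  # 368 + distance
        assert matrix.feature_names[-1] == "distance"
        expected = [compute_distance(r) for r in toy_ko_table.records]
        assert list(matrix.values[:, -1]) == expected

    def test_double_append_errors(self, toy_ko_table):
        matrix = encode_dataset(toy_ko_table, EncoderSpec("MM", with_distance=True))
        with pytest.raises(ValueError, match="already"):
            append_distance(matrix, list(toy_ko_table.records))

    def test_rows_are_order_independent(self, toy_ko_table):
        fwd = encode_dataset(toy_ko_table, EncoderSpec("OH")).values
        rev_table = toy_ko_table.replace_records(toy_ko_table.records[::-1])
        rev = encode_dataset(rev_table, EncoderSpec("OH")).values
        assert np.array_equal(fwd, rev[::-1])


class TestBiophysical:
    @pytest.mark.parametrize(
        "seq,expected", [("GGCC", 100.0), ("ATAT", 0.0), ("ACGT", 50.0)]
    )
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == expected

    def test_wallace_tm(self):
        # 2*(A+T) + 4*(G+C)
        assert melting_temperature("ACGT") == 12.0
        assert melting_temperature("AAAA") == 8.0

    def test_tm_monotone_under_a_to_g(self):
        assert melting_temperature("GAAA") - melting_temperature("AAAA") == 2.0

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            melting_temperature("")

    def test_folding_unavailable_sentinel(self):
        assert folding_energy("ACGT", executable="no-such-folder") is None

    @pytest.mark.skipif(shutil.which("RNAfold") is None, reason="no folding tool")
    def test_folding_oracle(self):
        # unstructured homopolymer folds to 0; a strong hairpin is negative
        assert folding_energy("A" * 23) == 0.0
        assert folding_energy("GGGGGGCCAAAAGGCCCCCC") < 0
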