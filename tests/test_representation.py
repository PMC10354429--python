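"""Positional encoding, Vars+PE and Mask representations."""

import numpy as np
import pytest

from evmp.align import make_record, reconstruct
from evmp.representation import (
    PEConfig,
    encode_base,
    encode_mask,
    encode_vars_pe,
    flatten_for_classical,
    mask_string,
    pe_matrix,
    positional_encoding,
)
from evmp.seq import Promoter, one_hot


class TestPositionalEncoding:
    def test_origin_alternates_sin_cos(self):
        assert positional_encoding(0, PEConfig(d_pe=4)).tolist() == [0, 1, 0, 1]
        assert positional_encoding(0).tolist() == [0, 1, 0, 1, 0]

    def test_entries_bounded(self):
        for p in (1, 17, 84):
            pe = positional_encoding(p)
            assert np.all(np.abs(pe) <= 1.0)
            assert np.linalg.norm(pe) <= np.sqrt(5)

    def test_injective_over_promoter_positions(self):
        mat = pe_matrix(85)
        dists = np.linalg.norm(mat[:, None, :] - mat[None, :, :], axis=2)
        off_diag = dists[~np.eye(85, dtype=bool)]
        assert off_diag.min() > 0

    def test_negative_position_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(-1)


class TestVarsPE:
    def _record(self, base_seq, var_seq, k, L=None):
        L = L or len(base_seq)
        return make_record(Promoter("b", base_seq), Promoter("v", var_seq),
                           k, L)

    def test_zero_mutations_all_zero(self):
        rec = self._record("AAAAA", "AAAAA", 3)
        assert np.all(encode_vars_pe(rec, max_sites=4) == 0)

    def test_single_site_block(self):
        """Every one of the k rows of a site block is the window base's
        one-hot plus the identical PE of the mutation-site position."""
        rec = self._record("AAAAA", "AATAA", 3)
        tensor = encode_vars_pe(rec, max_sites=4)
        pe2 = positional_encoding(2)
        expected = one_hot("ATA") + pe2
        assert np.allclose(tensor[:3], expected)
        assert np.all(tensor[3:] == 0)

    def test_blocks_sorted_by_position(self):
        rec = self._record("AAAAAA", "ATAATA", 1)
        tensor = encode_vars_pe(rec, max_sites=4)
        assert np.allclose(tensor[0], one_hot("T")[0] + positional_encoding(1))
        assert np.allclose(tensor[1], one_hot("T")[0] + positional_encoding(4))

    def test_pe_subtraction_recovers_window_one_hot(self):
        rec = self._record("AAAAA", "ACTAA", 3)
        tensor = encode_vars_pe(rec, max_sites=4)
        for j, mut in enumerate(rec.mutations):
            block = tensor[j * 3:(j + 1) * 3]
            recovered = block - positional_encoding(mut.site.position)
            assert np.allclose(recovered, one_hot(mut.window))

    def test_capacity_error(self):
        rec = self._record("AAAAA", "TTTTT", 1)
        with pytest.raises(ValueError, match="max_sites"):
            encode_vars_pe(rec, max_sites=3)

    def test_d_pe_must_match_channels(self):
        rec = self._record("AAAAA", "AATAA", 3)
        with pytest.raises(ValueError):
            encode_vars_pe(rec, PEConfig(d_pe=8), max_sites=4)


class TestMask:
    def _record(self, base_seq, var_seq, k):
        return make_record(Promoter("b", base_seq), Promoter("v", var_seq),
                           k, len(base_seq))

    @pytest.mark.parametrize("k,expected", [
        (1, "BTBBB"),   # only the mutated base survives
        (3, "ATABB"),   # window spills onto neighbours
    ])
    def test_masked_string(self, k, expected):
        rec = self._record("AAAAA", "ATAAA", k)
        assert mask_string(rec) == expected
        assert np.array_equal(encode_mask(rec), one_hot(expected))

    def test_zero_mutations_all_blank(self):
        rec = self._record("AAAAA", "AAAAA", 3)
        assert mask_string(rec) == "BBBBB"

    def test_huge_k_degenerates_to_full_variant(self):
        rec = self._record("AAAAA", "ATAAA", 12)
        assert mask_string(rec) == "ATAAA"

    def test_mask_preserves_mutation_information(self, small_library):
        """Overlaying the record's windows on the base recovers the variant
        — the Mask discards only bases shared with the base promoter."""
        lib, _ = small_library
        for variant in lib.variants[:25]:
            rec = make_record(lib.base, variant, 5, lib.pad_length)
            assert reconstruct(rec.base.sequence, rec.mutations) == \
                variant.sequence


class TestBaseEncodingAndFlattening:
    def test_base_without_pe_is_one_hot(self):
        mat = encode_base(Promoter("b", "AB"))
        assert mat.tolist() == [[1, 0, 0, 0, 0], [0, 0, 0, 0, 1]]

    def test_base_with_pe_adds_position_vector(self):
        mat = encode_base(Promoter("b", "A"), add_pe=True)
        assert np.allclose(mat, [[1, 1, 0, 1, 0]])

    def test_pe_separates_homopolymer_rows(self):
        mat = encode_base(Promoter("b", "A" * 85), add_pe=True)
        assert len(np.unique(mat.round(12), axis=0)) == 85

    def test_flatten_layout_and_purity(self):
        base = Promoter("b", "AA")
        rec = make_record(base, Promoter("v", "AA"), 1, 2)
        vec = flatten_for_classical(rec)
        assert vec.shape == (20,)
        assert np.array_equal(vec[:10], one_hot("AA").ravel())
        assert np.array_equal(vec[10:], one_hot("BB").ravel())
        assert np.array_equal(vec, flatten_for_classical(rec))

    def test_saved_tensors_match_in_memory_encoding(self, tmp_path,
                                                    small_records):
        from evmp.representation import save_representations

        save_representations(small_records[:6], tmp_path / "enc",
                             which="both", max_sites=18)
        data = np.load(tmp_path / "enc.npz")
        assert np.array_equal(
            data["mask"][2], encode_mask(small_records[2]))
        assert np.array_equal(
            data["vars_pe"][3],
            encode_vars_pe(small_records[3], max_sites=18))
        import json
        sidecar = json.loads((tmp_path / "enc.json").read_text())
        assert sidecar["n_records"] == 6
        assert sidecar["vars_pe"]["shape"] == list(data["vars_pe"].shape)

    def test_single_retained_base_changes_few_entries(self):
        base = Promoter("b", "AAAAA")
        r1 = make_record(base, Promoter("v1", "ATAAA"), 1, 5)
        r2 = make_record(base, Promoter("v2", "ACAAA"), 1, 5)
        diff = flatten_for_classical(r1) != flatten_for_classical(r2)
        assert 0 < diff.sum() <= 10
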