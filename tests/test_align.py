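"""Alignment, mutation extraction, k-mer windows and the equivalence
contract."""

import numpy as np
import pytest

from evmp.align import (
    AlignmentParams,
    ConsistencyError,
    EVMPRecord,
    KmerMutation,
    MutationSite,
    extract_sites,
    global_align,
    kmer_mutations,
    make_record,
    read_records,
    receptive_field,
    reconstruct,
    suggest_k,
    write_records,
)
from evmp.experiments import brute_force_align_score
from evmp.seq import Promoter


class TestGlobalAlign:
    def test_identity_alignment(self):
        aln = global_align("ACGT", "ACGT")
        assert (aln.a, aln.b) == ("ACGT", "ACGT")
        assert aln.score == 4.0

    def test_deletion_rendered_as_blank(self):
        aln = global_align("ACGT", "ACT")
        assert (aln.a, aln.b) == ("ACGT", "ACBT")
        assert aln.score == 1.0  # 3 matches - 1 gap

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_invalid_scoring_rejected(self):
        with pytest.raises(ValueError):
            AlignmentParams(match=-1, mismatch=1)

    def test_score_matches_exhaustive_oracle(self, rng):
        bases = np.array(list("ATCG"))
        for _ in range(60):
            a = "".join(rng.choice(bases, size=int(rng.integers(1, 10))))
            b = "".join(rng.choice(bases, size=int(rng.integers(1, 10))))
            assert global_align(a, b).score == brute_force_align_score(a, b)

    def test_score_matches_biopython(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        bases = np.array(list("ATCG"))
        for _ in range(40):
            a = "".join(rng.choice(bases, size=int(rng.integers(2, 15))))
            b = "".join(rng.choice(bases, size=int(rng.integers(2, 15))))
            assert global_align(a, b).score == aligner.score(a, b)


class TestSitesAndWindows:
    def test_no_mismatch_no_sites(self):
        assert extract_sites("AAAA", "AAAA") == []

    def test_single_substitution(self):
        sites = extract_sites("AAAA", "AATA")
        assert sites == [MutationSite(2, "A", "T")]

    def test_indel_blank_counts_as_site(self):
        assert extract_sites("ACGT", "ACBT") == [MutationSite(2, "G", "B")]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_sites("AAA", "AAAA")

    @pytest.mark.parametrize("variant,positions,k,windows", [
        ("AATAAA", [2], 3, ["ATA"]),            # interior window
        ("ATTAA", [1, 2], 3, ["ATT", "TTA"]),   # overlap kept per site
        ("TAAA", [0], 3, ["BTA"]),              # left boundary reads B
        ("AAAT", [3], 3, ["ATB"]),              # right boundary reads B
        ("ATAA", [1], 4, ["BATA"]),             # even k is left-heavy
    ])
    def test_window_index_arithmetic(self, variant, positions, k, windows):
        sites = [MutationSite(p, "C", variant[p]) for p in positions]
        muts = kmer_mutations(variant, sites, k)
        assert [m.window for m in muts] == windows

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            kmer_mutations("AAAA", [], 0)


class TestReconstruct:
    def test_no_mutations_identity(self):
        assert reconstruct("AAAAA", []) == "AAAAA"

    def test_single_window_overlay(self):
        mut = KmerMutation(MutationSite(2, "A", "T"), 3, "ATA")
        assert reconstruct("AAAAA", [mut]) == "AATAA"

    def test_conflicting_overlap_names_position(self):
        m1 = KmerMutation(MutationSite(1, "A", "T"), 3, "ATT")
        m2 = KmerMutation(MutationSite(2, "A", "C"), 3, "GCA")
        with pytest.raises(ConsistencyError, match="position"):
            reconstruct("AAAAA", [m1, m2])

    @pytest.mark.parametrize("k", [1, 3, 5, 8])
    def test_round_trip_on_generated_library(self, small_library, k):
        """<base, k-mer mutations> is equivalent to the variant for every k."""
        lib, _ = small_library
        for variant in lib.variants:
            rec = make_record(lib.base, variant, k, lib.pad_length)
            assert rec.variant_sequence() == variant.sequence
            assert rec.n_sites == sum(
                x != y for x, y in zip(lib.base.sequence, variant.sequence))

    def test_indel_variant_round_trips_in_aligned_coordinates(self):
        base = Promoter("b", "ACGTACGT")
        variant = Promoter("v", "ACGACGT")  # one deletion
        rec = make_record(base, variant, 3, 10)
        aligned_variant = rec.variant_sequence()
        assert aligned_variant.replace("B", "") == "ACGACGT"


class TestRecordProperties:
    def test_mutations_sorted_and_k_consistent(self):
        base = Promoter("b", "AAAAAA")
        m2 = KmerMutation(MutationSite(4, "A", "T"), 1, "T")
        m1 = KmerMutation(MutationSite(1, "A", "C"), 1, "C")
        rec = EVMPRecord(base, (m2, m1), "v", k=1)
        assert [m.site.position for m in rec.mutations] == [1, 4]

    def test_receptive_field_empty_and_interior(self, small_library):
        lib, _ = small_library
        base = lib.base
        empty = make_record(base, Promoter("same", base.sequence), 3,
                            lib.pad_length)
        assert receptive_field(empty) == 0.0

    def test_receptive_field_union_of_overlapping_windows(self):
        base = Promoter("b", "A" * 85)
        var = list(base.sequence)
        var[10], var[11] = "T", "C"
        rec = make_record(base, Promoter("v", "".join(var)), 3, 85)
        assert receptive_field(rec) == pytest.approx(4 / 85)

    def test_receptive_field_monotone_in_k(self, small_library):
        lib, _ = small_library
        v = lib.variants[0]
        fields = [receptive_field(make_record(lib.base, v, k, lib.pad_length))
                  for k in (1, 2, 3, 5, 8, 13)]
        assert all(a <= b for a, b in zip(fields, fields[1:]))
        for k, f in zip((1, 2, 3, 5, 8, 13), fields):
            n_sites = len(extract_sites(lib.base.sequence, v.sequence))
            assert f <= min(1.0, k * n_sites / lib.pad_length) + 1e-12


class TestSuggestK:
    @pytest.mark.parametrize("l,alpha,expected", [
        (80, 4, 20),    # the l / alpha heuristic
        (85, 85, 1),    # lower clamp
        (85, 3, 28),    # rounding of 28.33
        (85, 200, 1),   # clamp below 1
    ])
    def test_heuristic(self, l, alpha, expected):
        assert suggest_k(l, alpha) == expected

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            suggest_k(80, 0)


def test_jsonl_round_trip(tmp_path, small_records):
    path = tmp_path / "records.jsonl"
    write_records(small_records[:10], path)
    back = read_records(path)
    assert back == list(small_records[:10])
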