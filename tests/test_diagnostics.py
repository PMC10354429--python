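"""Average embedding distance and over-smoothing reports."""

import numpy as np
import pytest

from evmp.align import make_record
from evmp.diagnostics import (
    EmbeddingTrace,
    avg_embedding_distance,
    input_d0_evmp,
    input_d0_full,
    input_dispersion,
    oversmoothing_report,
)
from evmp.models import (
    EVMPRegressor,
    FullSequenceRegressor,
    UnsupportedOperationError,
)
from evmp.seq import Promoter, hamming


class TestAvgEmbeddingDistance:
    def test_three_four_five_triangle(self):
        t = EmbeddingTrace("l", [0.0, 0.0], [[3.0, 4.0]])
        assert avg_embedding_distance(t) == 2.5

    def test_collapsed_embeddings_give_zero(self):
        ref = np.array([1.0, 2.0, 3.0])
        t = EmbeddingTrace("l", ref, np.tile(ref, (5, 1)))
        assert avg_embedding_distance(t) == 0.0

    def test_mean_of_distances(self):
        t = EmbeddingTrace("l", [0.0, 0.0], [[3.0, 4.0], [0.0, 0.0]])
        assert avg_embedding_distance(t) == 1.25

    def test_matches_independent_loop(self, rng):
        for _ in range(5):
            n_l = int(rng.integers(2, 40))
            n = int(rng.integers(1, 30))
            ref = rng.normal(size=n_l)
            emb = rng.normal(size=(n, n_l))
            expected = np.mean(
                [np.sqrt(((e - ref) ** 2).sum()) for e in emb]) / n_l
            t = EmbeddingTrace("l", ref, emb)
            assert avg_embedding_distance(t) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingTrace("l", [0.0, 0.0], [[1.0, 2.0, 3.0]])


class TestInputDispersion:
    def test_full_stream_d0_closed_form(self, small_library):
        """One-hot rows differ at exactly the m mutated positions, each
        contributing 2 to the squared distance: d0 = mean(sqrt(2m)) / n0."""
        lib, _ = small_library
        d0 = input_d0_full(lib.variants, lib.base)
        m = np.array([hamming(lib.base.sequence, v.sequence)
                      for v in lib.variants])
        n0 = lib.pad_length * 5
        assert d0 == pytest.approx(np.mean(np.sqrt(2 * m)) / n0, abs=1e-12)

    def test_mutation_stream_more_dispersed_than_full(self, small_library):
        lib, _ = small_library
        d = input_dispersion(lib, k=5)
        assert d["d0_evmp"] > d["d0_full"]

    def test_zero_mutation_reference_is_origin(self, small_library):
        lib, _ = small_library
        base_rec = make_record(lib.base, Promoter("ref", lib.base.sequence),
                               5, lib.pad_length)
        records = [make_record(lib.base, v, 5, lib.pad_length)
                   for v in lib.variants[:10]]
        d0 = input_d0_evmp(records, base_rec)
        assert d0 > 0


class TestOversmoothingReport:
    def test_lstm_reports_time_steps(self, small_records):
        est = EVMPRegressor(family="lstm", k=3, epochs=2, hidden_size=8,
                            max_sites=18, random_state=0)
        est.fit(small_records)
        base_rec = make_record(small_records[0].base,
                               Promoter("ref", small_records[0].base.sequence),
                               3, small_records[0].length)
        table = oversmoothing_report(est, small_records[:20], base_rec)
        assert table.layer.iloc[0] == "input"
        assert len(table) == 1 + 3 * 18  # input + one row per time step
        assert (table.d_l >= 0).all()

    def test_transformer_reports_layers(self, small_records):
        est = EVMPRegressor(family="transformer", k=3, epochs=1,
                            hidden_size=8, n_layers=2, n_heads=2,
                            random_state=0)
        est.fit(small_records)
        base_rec = make_record(small_records[0].base,
                               Promoter("ref", small_records[0].base.sequence),
                               3, small_records[0].length)
        table = oversmoothing_report(est, small_records[:10], base_rec)
        assert list(table.layer) == ["input", "layer1", "layer2"]

    def test_classical_model_unsupported(self, small_records):
        est = EVMPRegressor(family="rf", k=3).fit(small_records)
        base_rec = make_record(small_records[0].base,
                               Promoter("ref", small_records[0].base.sequence),
                               3, small_records[0].length)
        with pytest.raises(UnsupportedOperationError):
            oversmoothing_report(est, small_records[:5], base_rec)

    def test_constant_encoder_gives_zero_distance(self, small_library):
        """If every input maps to the same embedding, d_l = 0 beyond the
        input layer (total over-smoothing)."""
        lib, _ = small_library
        est = FullSequenceRegressor(family="lstm", epochs=1, hidden_size=4,
                                    random_state=0).fit(lib.variants)
        # zero every encoder weight: all hidden states become identical
        est.net_.encoder.load_state_arrays(
            [np.zeros_like(a) for a in est.net_.encoder.state_arrays()])
        base_rec_like = lib.base
        table = oversmoothing_report(est, lib.variants[:10], base_rec_like)
        assert (table.d_l.iloc[1:] == 0).all()
        assert table.d_l.iloc[0] > 0
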