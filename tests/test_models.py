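"""Regressors: objective, fit capacity, determinism, persistence."""

import numpy as np
import pytest

from evmp.evaluation import mae
from evmp.models import (
    EVMPRegressor,
    FullSequenceRegressor,
    Prediction,
    UnsupportedOperationError,
    load_model,
    loss,
    train,
    train_baseline,
)


class TestObjective:
    def test_unregularized_is_sum_abs_error(self):
        preds = [Prediction("v", 0.5, 1.0)]
        assert loss(preds) == pytest.approx(0.5)

    def test_penalty_only(self):
        preds = [Prediction("v", 1.0, 1.0)]
        assert loss(preds, weights_norm_sq=2.0, lam=1.0) == pytest.approx(2.0)

    def test_combined(self):
        preds = [Prediction("a", 1.0, 1.0), Prediction("b", 2.0, 3.0)]
        assert loss(preds, weights_norm_sq=4.0, lam=0.5) == pytest.approx(3.0)

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError):
            loss([Prediction("v", 1.0)])

    def test_lambda_zero_ties_to_mae(self, small_records, small_library):
        lib, _ = small_library
        est = EVMPRegressor(family="rf", k=3, random_state=0)
        est.fit(small_records)
        preds = est.predictions(small_records)
        assert loss(preds) == pytest.approx(
            len(preds) * mae(preds), rel=1e-12)


class TestClassicalFamilies:
    def test_rf_recovers_noiseless_ground_truth(self, small_records,
                                                small_library):
        """On an additive noiseless library the Mask features preserve all
        mutation information, so the forest nearly interpolates."""
        lib, _ = small_library
        est = EVMPRegressor(family="rf", k=3, random_state=0)
        est.fit(small_records)
        # bootstrap averaging keeps a small floor at this library size
        assert mae(lib.strengths(), est.predict(small_records)) < 0.15

    @pytest.mark.parametrize("family", ["gbdt", "xgboost", "svm"])
    def test_other_families_fit_and_predict(self, family, small_records,
                                            small_library):
        lib, _ = small_library
        est = EVMPRegressor(family=family, k=3, random_state=0)
        est.fit(small_records)
        y_hat = est.predict(small_records)
        assert y_hat.shape == (len(small_records),)
        assert np.all(np.isfinite(y_hat))

    def test_classical_has_no_encoder_streams(self, small_records):
        est = EVMPRegressor(family="rf", k=3).fit(small_records)
        with pytest.raises(UnsupportedOperationError):
            est.embed_base(small_records[:2])
        with pytest.raises(UnsupportedOperationError):
            est.layer_trace(small_records[:2])

    def test_unknown_family_rejected(self, small_records):
        with pytest.raises(ValueError, match="family"):
            EVMPRegressor(family="cnn", k=3).fit(small_records)

    def test_k_mismatch_rejected(self, small_records):
        with pytest.raises(ValueError, match="k="):
            EVMPRegressor(family="rf", k=5).fit(small_records)


class TestDeepFamilies:
    def test_single_record_memorization(self, small_records):
        est = EVMPRegressor(family="lstm", k=3, epochs=300, batch_size=1,
                            learning_rate=1e-3, weight_decay=0.0,
                            val_fraction=0.0, patience=10**6, random_state=0)
        est.fit(small_records[:1])
        # the L1 objective oscillates at the step-size scale once converged;
        # memorisation means the loss *reaches* the tolerance
        assert min(h["train_loss"] for h in est.history_) < 1e-3

    def test_seeded_training_reproducible(self, small_records):
        def fit():
            return EVMPRegressor(family="lstm", k=3, epochs=5,
                                 random_state=3).fit(small_records)
        a, b = fit(), fit()
        assert np.array_equal(a.predict(small_records[:10]),
                              b.predict(small_records[:10]))
        assert a.history_ == b.history_

    def test_embeddings_deterministic_and_shaped(self, small_records):
        est = EVMPRegressor(family="lstm", k=3, epochs=2,
                            hidden_size=16, random_state=0)
        est.fit(small_records)
        e1 = est.embed_base(small_records[:4])
        e2 = est.embed_base(small_records[:4])
        assert np.array_equal(e1, e2)
        assert e1.shape == (4, 16)
        v = est.embed_vars(small_records[:4])
        assert v.shape == (4, 16)

    def test_embed_vars_distinguishes_mutation_content(self, small_records):
        est = EVMPRegressor(family="lstm", k=3, epochs=3,
                            random_state=0).fit(small_records)
        v = est.embed_vars(small_records[:6])
        assert len(np.unique(v.round(9), axis=0)) > 1

    def test_transformer_memorizes_small_set(self, small_records,
                                             small_library):
        lib, _ = small_library
        subset = small_records[:25]
        y = lib.strengths()[:25]
        est = EVMPRegressor(family="transformer", k=3, epochs=120,
                            batch_size=25, val_fraction=0.0, patience=10**6,
                            random_state=0)
        est.fit(subset, y)
        assert mae(y, est.predict(subset)) < 0.1

    def test_save_load_predictions_bit_identical(self, tmp_path,
                                                 small_records):
        est = EVMPRegressor(family="lstm", k=3, epochs=3, random_state=0)
        est.fit(small_records)
        est.save(tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert np.array_equal(est.predict(small_records),
                              back.predict(small_records))

    def test_classical_save_load_round_trip(self, tmp_path, small_records):
        est = EVMPRegressor(family="rf", k=3, random_state=0)
        est.fit(small_records)
        est.save(tmp_path / "rf")
        back = load_model(tmp_path / "rf")
        assert np.array_equal(est.predict(small_records),
                              back.predict(small_records))


class TestBaseline:
    def test_baseline_shares_evaluation_interface(self, small_library):
        lib, _ = small_library
        est = train_baseline(lib, family="rf", random_state=0)
        y_hat = est.predict(lib.variants)
        assert y_hat.shape == (len(lib.variants),)
        preds = est.predictions(lib.variants)
        assert all(p.y is not None for p in preds)

    def test_baseline_rf_fits_noiseless_library(self, small_library):
        lib, _ = small_library
        est = train_baseline(lib, family="rf", random_state=0)
        assert mae(lib.strengths(), est.predict(lib.variants)) < 0.15

    def test_baseline_encoder_excludes_head(self, small_library):
        lib, _ = small_library
        est = FullSequenceRegressor(family="lstm", epochs=2, hidden_size=8,
                                    random_state=0)
        est.fit(lib.variants)
        emb = est.embed_base(lib.variants[:3])
        assert emb.shape == (3, 8)  # encoder width, not the FFN head's

    def test_baseline_trace_has_input_layer(self, small_library):
        lib, _ = small_library
        est = FullSequenceRegressor(family="lstm", epochs=2, hidden_size=8,
                                    random_state=0).fit(lib.variants)
        trace = est.layer_trace(lib.variants[:5])
        assert trace[0][0] == "input"
        assert trace[0][1].shape == (5, lib.pad_length * 5)


def test_functional_wrappers(small_records, small_library):
    lib, _ = small_library
    est = train(small_records, family="rf", random_state=1)
    preds = est.predictions(small_records[:5])
    assert len(preds) == 5
    assert all(np.isfinite(p.y_hat) for p in preds)
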