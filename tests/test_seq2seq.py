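"""Architecture contracts: GRU equations, dense connections, attention, heads."""

import numpy as np
import pytest

from pulsemorph import _autodiff as ad
from pulsemorph._autodiff import Tensor
from pulsemorph.seq2seq import (
    Attention,
    GRUCell,
    ModelConfig,
    Seq2SeqModel,
    attention_op,
    gru_step,
)
from pulsemorph.training import init_weights

TINY = ModelConfig(encoder_units=(2, 3, 4), decoder_units=(4, 6, 8))


def _gru_oracle(cell, h_prev, x):
    """Direct evaluation of the GRU update equations, independent of the
    layer implementation."""
    sig = lambda v: 1 / (1 + np.exp(-v))
    z = sig(h_prev @ cell.Whz.data + x @ cell.Wtz.data + cell.bz.data)
    r = sig(h_prev @ cell.Whr.data + x @ cell.Wtr.data + cell.br.data)
    hc = np.tanh((r * h_prev) @ cell.Whh.data + x @ cell.Wth.data + cell.bh.data)
    return (1 - z) * h_prev + z * hc


class TestGruStep:
    def test_zero_weights_closed_form(self):
        # sigma(0) = 0.5, tanh(0) = 0 -> h = 0.5 * h_prev
        cell = GRUCell(2, 2, "c")
        h = gru_step(cell, np.array([[1.0, -1.0]]), np.zeros((1, 2)))
        assert np.allclose(h.data, [[0.5, -0.5]])

    def test_update_gate_saturated_gives_candidate(self):
        cell = GRUCell(2, 2, "c")
        cell.bz.data = np.full(2, 50.0)  # force z ~ 1
        rng = np.random.default_rng(0)
        for p in (cell.Wth, cell.Whh):
            p.data = rng.normal(size=p.data.shape)
        h_prev = rng.normal(size=(1, 2))
        x = rng.normal(size=(1, 2))
        h = gru_step(cell, h_prev, x)
        hc = np.tanh((0.5 * h_prev) @ cell.Whh.data + x @ cell.Wth.data)  # r = 0.5
        assert np.allclose(h.data, hc, atol=1e-10)

    def test_matches_equation_oracle_on_random_cases(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            cell = GRUCell(3, 4, "c")
            for p in cell.parameters():
                p.data = rng.normal(0, 0.5, p.data.shape)
            h_prev = rng.normal(size=(2, 4))
            x = rng.normal(size=(2, 3))
            h = gru_step(cell, h_prev, x)
            assert np.allclose(h.data, _gru_oracle(cell, h_prev, x), atol=1e-12)


class TestEncoder:
    def test_sequence_length_preserved(self):
        model = init_weights(Seq2SeqModel(TINY), seed=0)
        X = np.random.default_rng(0).random((2, 40, 2))
        enc, finals = model.encoder(X)
        assert enc.data.shape == (2, 40, 2 * TINY.encoder_units[-1])
        assert [f.data.shape[1] for f in finals] == [2 * u for u in TINY.encoder_units]

    def test_dense_connection_probes_first_layer(self):
        """Zeroing layer-1 weights must change layer-3's input, hence output."""
        model = init_weights(Seq2SeqModel(TINY), seed=1)
        X = np.random.default_rng(1).random((1, 30, 2))
        enc_before, _ = model.encoder(X)
        fwd0, bwd0 = model.encoder.layers[0]
        for p in fwd0.parameters() + bwd0.parameters():
            p.data = np.zeros_like(p.data)
        enc_after, _ = model.encoder(X)
        assert not np.allclose(enc_before.data, enc_after.data)

    def test_decoder_width_must_be_twice_encoder(self):
        with pytest.raises(ValueError):
            ModelConfig(encoder_units=(4, 20, 100), decoder_units=(8, 40, 100))


class TestAttention:
    def test_equal_scores_uniform_weights(self):
        att = Attention(2, 2)
        att.W.data = np.zeros((2, 2))
        enc = Tensor(np.random.default_rng(0).random((1, 4, 2)))
        a, c = att(Tensor(np.ones((1, 2))), enc)
        assert np.allclose(a.data, 0.25)

    def test_identity_score_closed_form(self):
        # W = I, h_t = [1,0], encoder steps [1,0] and [0,1]
        # -> scores (1, 0) -> softmax (e/(e+1), 1/(e+1))
        a, c = attention_op(np.eye(2), np.array([1.0, 0.0]),
                            np.array([[1.0, 0.0], [0.0, 1.0]]))
        e = np.e
        assert np.allclose(a, [e / (e + 1), 1 / (e + 1)])
        assert np.allclose(c, a @ np.array([[1.0, 0.0], [0.0, 1.0]]))

    def test_weights_sum_to_one(self):
        att = Attention(4, 4)
        att.W.data = np.random.default_rng(2).normal(size=(4, 4))
        enc = Tensor(np.random.default_rng(3).random((3, 7, 4)))
        a, _ = att(Tensor(np.random.default_rng(4).random((3, 4))), enc)
        assert np.allclose(a.data.sum(axis=1), 1.0)


class TestDecoderAndModel:
    def test_first_step_uses_ones_start_token(self):
        model = init_weights(Seq2SeqModel(TINY), seed=0)
        assert np.all(model.y0(3).data == 1.0)

    def test_class_probabilities_sum_to_one(self):
        model = init_weights(Seq2SeqModel(TINY), seed=0)
        X = np.random.default_rng(0).random((2, 20, 2))
        _v, probs, _a = model.predict_sequence(X, np.ones((2, 2)), 9)
        assert np.allclose(probs.sum(axis=2), 1.0)

    def test_predict_runs_exactly_T_steps(self):
        model = init_weights(Seq2SeqModel(TINY), seed=0)
        X = np.random.default_rng(0).random((1, 20, 2))
        v, probs, att = model.predict_sequence(X, np.ones((1, 2)), 16)
        assert v.shape == (1, 16) and probs.shape == (1, 16, 4)
        assert att.shape == (1, 16, 20)

    def test_attention_map_rows_sum_to_one(self):
        model = init_weights(Seq2SeqModel(TINY), seed=0)
        X = np.random.default_rng(0).random((1, 20, 2))
        _v, _p, att = model.predict_sequence(X, np.ones((1, 2)), 8)
        assert np.allclose(att.sum(axis=2), 1.0)

    def test_deterministic_given_same_inputs(self):
        model = init_weights(Seq2SeqModel(TINY), seed=0)
        X = np.random.default_rng(0).random((1, 20, 2))
        v1, p1, _ = model.predict_sequence(X, np.ones((1, 2)), 8)
        v2, p2, _ = model.predict_sequence(X, np.ones((1, 2)), 8)
        assert np.array_equal(v1, v2) and np.array_equal(p1, p2)

    def test_teacher_forcing_differs_from_autoregressive(self):
        model = init_weights(Seq2SeqModel(TINY), seed=0)
        rng = np.random.default_rng(1)
        X = rng.random((1, 20, 2))
        teacher = rng.random((1, 8, 5))
        with_t, _, _ = model.forward_teacher(X, np.ones((1, 2)), teacher, 8)
        v_auto, _, _ = model.predict_sequence(X, np.ones((1, 2)), 8)
        assert not np.allclose(with_t.data, v_auto)

    def test_di_mismatch_raises(self):
        no_di = ModelConfig(encoder_units=(2, 3), decoder_units=(4, 6), use_di=False)
        model = init_weights(Seq2SeqModel(no_di), seed=0)
        X = np.random.default_rng(0).random((1, 10, 2))
        with pytest.raises(ValueError):
            model.predict_sequence(X, np.ones((1, 2)), 4)
        di_model = init_weights(Seq2SeqModel(TINY), seed=0)
        with pytest.raises(ValueError):
            di_model.predict_sequence(X, None, 4)

    def test_fused_teacher_path_matches_stepwise(self):
        """The vectorized teacher-forced pass must agree with per-step decoding."""
        model = init_weights(Seq2SeqModel(TINY), seed=2)
        rng = np.random.default_rng(2)
        X = rng.random((2, 15, 2))
        teacher = rng.random((2, 6, 5))
        v_fast, p_fast, a_fast = model.forward_teacher(X, np.ones((2, 2)), teacher, 6)
        with ad.no_grad():
            enc, finals = model.encoder(X)
            values, probs, atts, _ = model.decode(enc, finals, np.ones((2, 2)), 6,
                                                  teacher_inputs=teacher)
        v_slow = np.concatenate([t.data for t in values], axis=1)
        p_slow = np.stack([t.data for t in probs], axis=1)
        assert np.allclose(v_fast.data, v_slow, atol=1e-10)
        assert np.allclose(p_fast.data, p_slow, atol=1e-10)

    def test_parameter_count_full_scale_bounded(self):
        model = Seq2SeqModel(ModelConfig())
        assert model.n_parameters() < 2_000_000

    def test_initialized_outputs_finite_for_unit_inputs(self):
        model = init_weights(Seq2SeqModel(TINY), seed=7)
        X = np.ones((1, 30, 2))
        v, p, a = model.predict_sequence(X, np.ones((1, 2)), 10)
        assert np.isfinite(v).all() and np.isfinite(p).all() and np.isfinite(a).all()

    def test_checkpoint_roundtrip(self, tmp_path):
        model = init_weights(Seq2SeqModel(TINY), seed=0)
        model.save(tmp_path / "ckpt", extra={"T": 12})
        back, meta = Seq2SeqModel.load(tmp_path / "ckpt")
        assert meta["T"] == 12
        for p, q in zip(model.parameters(), back.parameters()):
            assert np.array_equal(p.data, q.data)
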