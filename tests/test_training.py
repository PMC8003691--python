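"""Losses against brute-force oracles, init scheme, schedule, splits."""

import numpy as np
import pytest

from pulsemorph.seq2seq import ModelConfig, Seq2SeqModel
from pulsemorph.training import (
    LRSchedule,
    TrainConfig,
    class_ce,
    init_weights,
    make_splits,
    masked_mse,
    one_hot,
    total_loss,
)


def _mse_loop(truth, pred, mask):
    """Brute-force per-element evaluation of the masked value loss."""
    total = 0.0
    for j in range(truth.shape[0]):
        M = int(mask[j].sum())
        s = 0.0
        for i in range(M):
            s += (truth[j, i] - pred[j, i]) ** 2
        total += s / M
    return total / truth.shape[0]


def _ce_loop(onehot, probs, eps=1e-8):
    """Brute-force per-element categorical cross-entropy."""
    n, T, C = onehot.shape
    total = 0.0
    for j in range(n):
        for i in range(T):
            for c in range(C):
                total -= onehot[j, i, c] * np.log(max(probs[j, i, c], eps))
    return total / (n * T)


class TestMaskedMse:
    def test_hand_computed_example(self):
        # truth [1,2,3,4], pred [1,2,5,4], M=3 -> (0+0+4)/3
        v = masked_mse([1.0, 2, 3, 4], [1.0, 2, 5, 4], [1, 1, 1, 0])
        assert v == pytest.approx(4 / 3)

    def test_perfect_prediction_zero(self):
        x = np.random.default_rng(0).random((3, 10))
        assert masked_mse(x, x, np.ones_like(x)) == 0.0

    def test_outer_mean_over_samples(self):
        truth = np.zeros((2, 2))
        pred = np.array([[1.0, 1.0], [np.sqrt(3), np.sqrt(3)]])
        assert masked_mse(truth, pred, np.ones((2, 2))) == pytest.approx(2.0)

    def test_matches_bruteforce_loop_on_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n, T = rng.integers(1, 6), rng.integers(2, 20)
            truth = rng.normal(size=(n, T))
            pred = rng.normal(size=(n, T))
            mask = np.zeros((n, T))
            for j in range(n):
                mask[j, : rng.integers(1, T + 1)] = 1
            fast = masked_mse(truth, pred, mask)
            slow = _mse_loop(truth, pred, mask)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            masked_mse(np.ones((1, 4)), np.ones((1, 4)), np.zeros((1, 4)))


class TestClassCe:
    def test_perfect_one_hot_zero(self):
        oh = one_hot(np.array([[0, 1, 2, 3]]))
        assert class_ce(oh, oh.clip(1e-8, 1.0)) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_ln4(self):
        oh = one_hot(np.array([[0, 1, 2, 3]]))
        probs = np.full((1, 4, 4), 0.25)
        assert class_ce(oh, probs) == pytest.approx(np.log(4))

    def test_clipping_bounds_zero_probability(self):
        oh = one_hot(np.array([[0]]))
        probs = np.array([[[0.0, 1.0, 0.0, 0.0]]])
        assert class_ce(oh, probs) == pytest.approx(-np.log(1e-8))

    def test_matches_bruteforce_loop_on_random_cases(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n, T = rng.integers(1, 5), rng.integers(2, 12)
            oh = one_hot(rng.integers(0, 4, size=(n, T)))
            logits = rng.normal(size=(n, T, 4))
            probs = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
            assert class_ce(oh, probs) == pytest.approx(_ce_loop(oh, probs), rel=1e-10)

    def test_minimized_only_at_truth(self):
        oh = one_hot(np.array([[1, 2]]))
        wrong = one_hot(np.array([[2, 1]])).clip(1e-8, 1)
        assert class_ce(oh, wrong) > class_ce(oh, oh.clip(1e-8, 1))


class TestTotalLoss:
    def test_paper_lambda(self):
        assert total_loss(1.0, 2.0) == pytest.approx(1.02)

    def test_zero_ce_reduces_to_mse(self):
        assert total_loss(0.7, 0.0) == 0.7

    def test_lambda_zero_escape_hatch(self):
        assert total_loss(0.7, 5.0, lam=0.0) == 0.7


@pytest.fixture(scope="module")
def model():
    return init_weights(
        Seq2SeqModel(ModelConfig(encoder_units=(4, 8), decoder_units=(8, 16))), seed=3
    )


class TestInit:
    def test_head_bound_is_inverse_sqrt_fan_in(self, model):
        W = model.decoder.head_value.W
        w = 1.0 / np.sqrt(W.data.shape[0])
        assert np.abs(W.data).max() <= w
        # a uniform draw over [-w, w] should come close to the bound
        assert np.abs(W.data).max() > 0.8 * w

    def test_gru_input_bound_is_inverse_sqrt_units(self, model):
        cell = model.decoder.layers[1]
        k = 1.0 / np.sqrt(cell.units)
        for p in (cell.Wtz, cell.Wtr, cell.Wth):
            assert np.abs(p.data).max() <= k

    def test_recurrent_matrices_orthogonal(self, model):
        for cell in model.decoder.layers:
            for p in (cell.Whz, cell.Whr, cell.Whh):
                assert np.allclose(p.data.T @ p.data, np.eye(cell.units), atol=1e-10)

    def test_biases_zero(self, model):
        assert np.all(model.decoder.layers[0].bz.data == 0)

    def test_deterministic_given_seed(self):
        cfg = ModelConfig(encoder_units=(2, 3), decoder_units=(4, 6))
        m1 = init_weights(Seq2SeqModel(cfg), seed=5)
        m2 = init_weights(Seq2SeqModel(cfg), seed=5)
        for p, q in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(p.data, q.data)


class TestSchedule:
    def test_decreasing_losses_keep_lr(self):
        s = LRSchedule(1e-3)
        for loss in np.linspace(1.0, 0.5, 40):
            lr, stop = s.update(loss)
        assert lr == 1e-3 and not stop

    def test_25_flat_epochs_halve_lr(self):
        s = LRSchedule(1e-3)
        s.update(1.0)
        for _ in range(25):
            lr, stop = s.update(1.0)
        assert lr == pytest.approx(5e-4) and not stop

    def test_50_flat_epochs_stop(self):
        s = LRSchedule(1e-3)
        s.update(1.0)
        stop = False
        for _ in range(50):
            _lr, stop = s.update(1.0)
        assert stop

    def test_improvement_resets_counter(self):
        s = LRSchedule(1e-3)
        s.update(1.0)
        for _ in range(24):
            s.update(1.0)
        s.update(0.9)  # reset
        for _ in range(24):
            lr, stop = s.update(0.9)
        assert lr == 1e-3 and not stop

    def test_invalid_patience_ordering_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(patience_decay=50, patience_stop=50)


class TestTrainLoop:
    @staticmethod
    def _tiny_setup(training_setup):
        from pulsemorph.training import train

        samples, _scaler, _T, _products = training_setup
        cfg = ModelConfig(encoder_units=(2, 4), decoder_units=(4, 8))
        return train, samples[:4], cfg

    def test_loss_history_reproducible_given_seed(self, training_setup):
        from pulsemorph.training import TrainConfig, train

        samples, _sc, _T, _p = training_setup
        cfg = ModelConfig(encoder_units=(2, 4), decoder_units=(4, 8))
        tc = TrainConfig(max_epochs=2, batch_size=2, seed=5)
        histories = []
        for _ in range(2):
            model = init_weights(Seq2SeqModel(cfg), seed=1)
            res = train(model, samples[:4], tc)
            histories.append([h[1] for h in res.history])
        assert histories[0] == histories[1]

    def test_batch_size_honoured_with_smaller_last_batch(self, training_setup):
        from pulsemorph.training import _batch_arrays

        samples, _sc, _T, _p = training_setup
        X, di, V, oh, M, teacher = _batch_arrays(samples, [0, 1, 2], epoch=0, seed=0,
                                                 n_classes=4)
        assert X.shape[0] == 3 and teacher.shape[2] == 5

    def test_divergence_aborts_with_diagnostic(self, training_setup):
        from pulsemorph.training import TrainConfig, train

        samples, _sc, _T, _p = training_setup
        model = init_weights(Seq2SeqModel(ModelConfig(encoder_units=(2, 4),
                                                      decoder_units=(4, 8))), seed=1)
        model.decoder.head_value.W.data[:] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            train(model, samples[:2], TrainConfig(max_epochs=1, batch_size=2))

    def test_di_model_requires_demographics(self, training_setup):
        from dataclasses import replace

        from pulsemorph.training import TrainConfig, train

        samples, _sc, _T, _p = training_setup
        stripped = [replace(s, di=None) for s in samples[:2]]
        model = init_weights(Seq2SeqModel(ModelConfig(encoder_units=(2, 4),
                                                      decoder_units=(4, 8))), seed=1)
        with pytest.raises(ValueError):
            train(model, stripped, TrainConfig(max_epochs=1))


@pytest.fixture(scope="module")
def manifest():
    import pandas as pd

    rows = []
    for s in range(20):
        for k in range(5):
            rows.append({"subject_id": f"s{s:02d}", "segment_id": f"s{s:02d}-{k}"})
    return pd.DataFrame(rows)


class TestSplits:
    def test_mixno_subject_disjoint_every_fold(self, manifest):
        split = make_splits(manifest, "Mixno", seed=0)
        for train_m, test_m in split.folds:
            assert not (set(train_m.subject_id) & set(test_m.subject_id))

    def test_mixno_test_fraction_20pct_subjects(self, manifest):
        split = make_splits(manifest, "Mixno+DI", seed=1)
        for _train_m, test_m in split.folds:
            assert test_m.subject_id.nunique() == 4

    def test_mixno_folds_cover_all_subjects(self, manifest):
        split = make_splits(manifest, "Mixno", seed=2)
        covered = set()
        for _t, test_m in split.folds:
            covered |= set(test_m.subject_id)
        assert len(covered) == 20

    def test_mixyes_test_fraction_20pct_segments(self, manifest):
        split = make_splits(manifest, "Mixyes+DI", seed=0)
        for _train_m, test_m in split.folds:
            assert len(test_m) == 20

    def test_too_few_subjects_raises(self, manifest):
        with pytest.raises(ValueError):
            make_splits(manifest[manifest.subject_id < "s04"], "Mixno", seed=0)

    def test_unknown_scenario_rejected(self, manifest):
        with pytest.raises(ValueError):
            make_splits(manifest, "Mixmaybe", seed=0)
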