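"""Loss masking, MCC, gradient accumulation and early stopping."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

import contactnet.training as training
from contactnet.augment import AugmentConfig, TrainingExample
from contactnet.features import FeatureTensor, bounds_channel, separation_channel
from contactnet.network import ModelConfig, build_model
from contactnet.training import (
    TrainConfig,
    example_loss_and_grad,
    masked_bce,
    mcc,
    pair_mask,
    train,
)

TINY = ModelConfig(in_channels=3, width=4, n_blocks=1, dilation_schedule=(1,), kernel=3, dtype="float64")


def random_example(rng, L=12, C=3, density=0.2):
    y = np.triu((rng.random((L, L)) < density).astype(np.int8), 5)
    y = y + y.T
    data = rng.normal(size=(C, L, L))
    data[-2] = separation_channel(L)
    data[-1] = bounds_channel(L)
    x = FeatureTensor(data, [f"c{i}" for i in range(C - 2)] + ["separation", "bounds"])
    return TrainingExample(x=x, y=y, loop_mask=np.zeros(L, dtype=bool))


class TestMaskedBce:
    def test_perfect_confident_predictions(self):
        L = 12
        rng = np.random.default_rng(0)
        ex = random_example(rng, L)
        pred = ex.y.astype(float)
        assert masked_bce(pred, ex.y) <= 1e-6

    def test_short_range_pairs_ignored(self):
        L = 12
        rng = np.random.default_rng(1)
        ex = random_example(rng, L)
        pred = np.full((L, L), 0.5)
        base = masked_bce(pred, ex.y)
        tweaked = pred.copy()
        idx = np.arange(L)
        close = np.abs(idx[:, None] - idx[None, :]) <= 4
        tweaked[close] = 0.999
        assert masked_bce(tweaked, ex.y) == pytest.approx(base, abs=1e-15)

    def test_uniform_half_is_ln2(self):
        L = 10
        truth = np.zeros((L, L), dtype=np.int8)
        assert masked_bce(np.full((L, L), 0.5), truth) == pytest.approx(np.log(2))

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="separation"):
            masked_bce(np.zeros((4, 4)), np.zeros((4, 4)), min_sep=5)


class TestMcc:
    def test_perfect_agreement(self):
        rng = np.random.default_rng(2)
        ex = random_example(rng)
        assert mcc(ex.y.astype(float), ex.y) == pytest.approx(1.0)

    def test_perfect_inversion(self):
        rng = np.random.default_rng(3)
        ex = random_example(rng)
        assert mcc(1.0 - ex.y, ex.y) == pytest.approx(-1.0)

    def test_hand_built_confusion(self):
        # TP=3, FP=1, FN=2, TN=10 laid out along an eligible diagonal band
        L = 30
        pred = np.zeros((L, L))
        truth = np.zeros((L, L), dtype=np.int8)
        cells = [(i, i + 10) for i in range(16)]
        for k, (i, j) in enumerate(cells):
            if k < 3:
                pred[i, j], truth[i, j] = 1.0, 1
            elif k < 4:
                pred[i, j] = 1.0
            elif k < 6:
                truth[i, j] = 1
        truth = np.triu(truth) + np.triu(truth).T
        tp, fp, fn = 3, 1, 2
        tn = pair_mask(L, 5).sum() - tp - fp - fn
        expect = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert mcc(pred, truth) == pytest.approx(expect, abs=1e-12)

    def test_degenerate_margin_returns_zero(self):
        L = 12
        assert mcc(np.zeros((L, L)), np.zeros((L, L), dtype=np.int8)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        ex = random_example(rng, L=20, density=0.3)
        pred = rng.random((20, 20))
        mask = pair_mask(20, 5)
        expect = matthews_corrcoef(ex.y[mask], pred[mask] >= 0.5)
        assert mcc(pred, ex.y) == pytest.approx(expect, abs=1e-12)


class TestGradients:
    def test_accumulated_gradients_match_finite_differences(self):
        """Per-example accumulation reproduces the numerical gradient of the
        batch loss (mean of per-example means) to 1e-6."""
        rng = np.random.default_rng(7)
        batch = [random_example(rng, L=10) for _ in range(3)]
        model = build_model(TINY, seed=0)
        scale = 1.0 / len(batch)

        for p in model.params():
            p.zero_grad()
        for ex in batch:
            example_loss_and_grad(model, ex, 5, scale)

        def batch_loss():
            losses = []
            for ex in batch:
                z = model.forward_logits(ex.x)
                zs = 0.5 * (z + z.T)
                from contactnet.nn import sigmoid

                losses.append(masked_bce(sigmoid(zs), ex.y))
            return np.mean(losses)

        check_rng = np.random.default_rng(1)
        h = 1e-6
        for p in model.params():
            flat = p.data.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in check_rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = batch_loss()
                flat[idx] = orig - h
                lm = batch_loss()
                flat[idx] = orig
                assert gflat[idx] == pytest.approx((lp - lm) / (2 * h), abs=1e-6)

    def test_overfit_single_example(self):
        rng = np.random.default_rng(8)
        ex = random_example(rng, L=12)
        model = build_model(TINY, seed=1)
        cfg = TrainConfig(batch_size=1, max_epochs=8, patience=100, seed=0)
        result = train(model, [ex], [ex], cfg, AugmentConfig.disabled())
        losses = [h["train_loss"] for h in result.history]
        assert losses[-1] < losses[0]


class TestEarlyStopping:
    def test_stops_quickly_when_metric_frozen(self, monkeypatch):
        rng = np.random.default_rng(9)
        ex = random_example(rng, L=10)
        model = build_model(TINY, seed=2)
        monkeypatch.setattr(training, "evaluate_mcc", lambda *a, **k: 0.0)
        cfg = TrainConfig(batch_size=1, max_epochs=50, patience=1, seed=0)
        result = train(model, [ex], [ex], cfg, AugmentConfig.disabled())
        assert len(result.history) <= 2

    def test_returns_best_mcc_checkpoint(self, monkeypatch):
        rng = np.random.default_rng(10)
        ex = random_example(rng, L=10)
        model = build_model(TINY, seed=3)
        schedule = iter([0.1, 0.6, 0.3, 0.2, 0.1])
        snapshots = []

        def fake_eval(model_, examples, cfg_):
            snapshots.append({k: v.copy() for k, v in model_.state_dict().items()})
            return next(schedule)

        monkeypatch.setattr(training, "evaluate_mcc", fake_eval)
        cfg = TrainConfig(batch_size=1, max_epochs=5, patience=3, seed=0)
        result = train(model, [ex], [ex], cfg, AugmentConfig.disabled())
        assert result.best_epoch == 1
        assert result.best_mcc == pytest.approx(0.6)
        best = snapshots[1]
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, best[k])

    def test_history_and_summary(self):
        rng = np.random.default_rng(11)
        ex = random_example(rng, L=10)
        model = build_model(TINY, seed=4)
        cfg = TrainConfig(batch_size=1, max_epochs=2, patience=10, seed=0)
        result = train(model, [ex], [ex], cfg)
        assert len(result.history) == 2
        text = result.summary()
        assert "val_mcc" in text and "best epoch" in text


def test_train_rejects_empty_sets():
    model = build_model(TINY, seed=0)
    with pytest.raises(ValueError):
        train(model, [], [], TrainConfig())
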