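"""Unit tests for the NumPy recognition network.

Gradient checks run under the ``float64_model`` fixture (which flips the
module-level DTYPE) so central differences resolve to ~1e-9 instead of
float32 rounding noise.
"""

import numpy as np
import pytest

import emoradar.model as M
from emoradar.model import (
    EMOTIONS, Adam, EmotionSample, EmotionNet, TrainConfig, TrainHistory,
    branch_1d_output_length, branch_2d_output_size, cross_entropy,
    evaluate_accuracy, fuse_features, predict, predict_proba, softmax,
    samples_to_arrays, train,
)


def _check_layer(layer, x, tol=1e-6, n_probe=40):
    """Compare analytic gradients with central differences (sampled entries)."""
    rng = np.random.default_rng(99)
    y0 = layer.forward(x.copy(), train=True)
    wout = rng.normal(size=y0.shape).astype(x.dtype)

    def loss():
        return float((layer.forward(x, train=True) * wout).sum())

    for p in layer.params():
        p.grad[...] = 0.0
    layer.forward(x, train=True)
    dx = layer.backward(wout)
    assert dx.shape == x.shape

    eps = 1e-6

    def probe(arr, grad):
        flat, gflat = arr.reshape(-1), grad.reshape(-1)
        idxs = rng.choice(flat.size, size=min(n_probe, flat.size),
                          replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            lp = loss()
            flat[i] = orig - eps
            lm = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert gflat[i] == pytest.approx(num, abs=tol * max(1, abs(num)))

    probe(x, dx)
    for p in layer.params():
        probe(p.value, p.grad)


class TestShapes:
    def test_branch_output_oracles(self):
        assert branch_1d_output_length(1200) == 9
        assert branch_2d_output_size(227) == 3

    def test_parameter_count(self):
        net = EmotionNet(series_length=1200, n_keyframes=8, seed=0)
        assert net.n_parameters() == 251012
        assert net.t_steps == 9
        assert net.fused_width == 64 + 64 + 96

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            EmotionNet(series_length=60)
        EmotionNet(series_length=88)   # documented minimum works

    def test_keyframes_required(self):
        with pytest.raises(ValueError):
            EmotionNet(series_length=1200, n_keyframes=0)

    def test_forward_logits_shape(self):
        rng = np.random.default_rng(0)
        net = EmotionNet(series_length=128, n_keyframes=1, seed=0)
        resp = rng.normal(size=(2, 128))
        heart = rng.normal(size=(2, 128))
        faces = rng.normal(size=(2, 1, 227, 227, 3))
        logits = net.forward(resp, heart, faces, train=False)
        assert logits.shape == (2, 4)


class TestGradients:
    def test_dense(self, float64_model):
        rng = np.random.default_rng(0)
        _check_layer(M.Dense(5, 3, rng), rng.normal(size=(4, 5)))

    def test_conv1d(self, float64_model):
        rng = np.random.default_rng(1)
        _check_layer(M.Conv1D(2, 3, kernel=5, stride=2, rng=rng),
                     rng.normal(size=(2, 13, 2)))

    def test_conv2d(self, float64_model):
        rng = np.random.default_rng(2)
        _check_layer(M.Conv2D(2, 3, kernel=(3, 3), rng=rng),
                     rng.normal(size=(2, 6, 7, 2)))

    def test_maxpool1d(self, float64_model):
        rng = np.random.default_rng(3)
        _check_layer(M.MaxPool1D(2, 2), rng.normal(size=(2, 9, 3)))

    def test_maxpool2d(self, float64_model):
        rng = np.random.default_rng(4)
        _check_layer(M.MaxPool2D(4, 4), rng.normal(size=(2, 9, 10, 3)))

    def test_batchnorm(self, float64_model):
        rng = np.random.default_rng(5)
        _check_layer(M.BatchNorm(3), rng.normal(size=(4, 6, 3)))

    def test_elu(self, float64_model):
        rng = np.random.default_rng(6)
        _check_layer(M.ELU(), rng.normal(size=(3, 5, 2)))

    def test_global_avg_pool(self, float64_model):
        rng = np.random.default_rng(7)
        _check_layer(M.GlobalAvgPool2D(), rng.normal(size=(2, 4, 5, 3)))

    def test_gru(self, float64_model):
        rng = np.random.default_rng(8)
        _check_layer(M.GRU(4, 6, rng), rng.normal(size=(3, 7, 4)),
                     tol=1e-5)


class TestPooling:
    def test_maxpool2d_rejects_nonpower(self):
        with pytest.raises(ValueError):
            M.MaxPool2D(3, 3)
        with pytest.raises(ValueError):
            M.MaxPool2D(4, 2)

    def test_maxpool1d_rejects_overlap(self):
        with pytest.raises(ValueError):
            M.MaxPool1D(4, 2)

    def test_maxpool2d_tie_routes_to_earliest(self):
        pool = M.MaxPool2D(2, 2)
        x = np.ones((1, 4, 4, 1), dtype=M.DTYPE)
        y = pool.forward(x)
        np.testing.assert_array_equal(y, np.ones((1, 2, 2, 1)))
        dx = pool.backward(np.ones_like(y))
        # all-equal windows: the gradient must land on exactly one element
        # per window, the top-left one
        expected = np.zeros_like(x)
        expected[:, 0::2, 0::2] = 1.0
        np.testing.assert_array_equal(dx, expected)

    def test_maxpool2d_floor_crop(self):
        pool = M.MaxPool2D(2, 2)
        x = np.arange(1 * 5 * 5 * 1, dtype=M.DTYPE).reshape(1, 5, 5, 1)
        y = pool.forward(x)
        assert y.shape == (1, 2, 2, 1)
        dx = pool.backward(np.ones_like(y))
        assert dx.shape == x.shape
        assert np.all(dx[:, 4] == 0) and np.all(dx[:, :, 4] == 0)


class TestLossAndOptimizer:
    def test_softmax_rows_sum_to_one(self):
        p = softmax(np.array([[10.0, 0.0, -5.0, 3.0], [0.0, 0.0, 0.0, 0.0]]))
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        np.testing.assert_allclose(p[1], 0.25)

    def test_cross_entropy_uniform(self):
        logits = np.zeros((3, 4))
        loss, grad = cross_entropy(logits, np.array([0, 1, 2]))
        assert loss == pytest.approx(np.log(4))
        np.testing.assert_allclose(grad.sum(axis=1), 0.0, atol=1e-7)

    def test_cross_entropy_gradient_numeric(self, float64_model):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(5, 4))
        labels = np.array([0, 3, 1, 2, 2])
        _, grad = cross_entropy(logits, labels)
        eps = 1e-6
        for i in range(5):
            for j in range(4):
                lp = logits.copy()
                lp[i, j] += eps
                lm = logits.copy()
                lm[i, j] -= eps
                num = (cross_entropy(lp, labels)[0]
                       - cross_entropy(lm, labels)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-7)

    def test_adam_minimizes_quadratic(self):
        p = M.Param(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            p.grad = 2 * p.value
            opt.step()
        assert np.max(np.abs(p.value)) < 1e-2


class TestFusion:
    def test_resample_indices(self):
        idx = M._face_resample_indices(2, 9)
        assert idx.shape == (9,)
        assert idx.min() == 0 and idx.max() == 1
        assert np.all(np.diff(idx) >= 0)

    def test_fuse_shapes(self):
        r = np.zeros((2, 9, 64))
        h = np.zeros((2, 9, 64))
        f = np.zeros((2, 3, 96))
        fused = fuse_features(r, h, f)
        assert fused.shape == (2, 9, 224)

    def test_fuse_mismatch(self):
        with pytest.raises(ValueError):
            fuse_features(np.zeros((2, 9, 64)), np.zeros((2, 8, 64)),
                          np.zeros((2, 3, 96)))


def _toy_samples(n, length=128, f_frames=1, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(length) / 20.0
    out = []
    for i in range(n):
        lab = EMOTIONS[i % 4]
        f_r = 0.15 + 0.1 * (i % 4)
        f_h = 1.0 + 0.2 * (i % 4)
        kf = np.full((f_frames, 227, 227, 3), 40 * (i % 4), dtype=np.uint8)
        out.append(EmotionSample(
            respiration=np.sin(2 * np.pi * f_r * t) + 0.01 * rng.normal(size=length),
            heartbeat=np.sin(2 * np.pi * f_h * t) + 0.01 * rng.normal(size=length),
            keyframes=kf, label=lab, subject_id=i % 3, sample_id=f"s{i}"))
    return out


class TestNetBehavior:
    def test_eval_forward_deterministic(self):
        net = EmotionNet(series_length=128, n_keyframes=1, seed=1)
        s = _toy_samples(2)
        a = predict_proba(net, s)
        b = predict_proba(net, s)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, rtol=1e-5)

    def test_zero_all_modalities_ignores_input(self):
        net = EmotionNet(series_length=128, n_keyframes=1, seed=1)
        s = _toy_samples(2)
        zeroed = ("respiration", "heartbeat", "face")
        probs = predict_proba(net, s, zero_modalities=zeroed)
        np.testing.assert_allclose(probs[0], probs[1], atol=1e-6)

    def test_zeroing_one_modality_changes_output(self):
        net = EmotionNet(series_length=128, n_keyframes=1, seed=1)
        s = _toy_samples(2)
        full = predict_proba(net, s)
        no_face = predict_proba(net, s, zero_modalities=("face",))
        assert np.abs(full - no_face).max() > 1e-6

    def test_save_load_round_trip(self, tmp_path):
        net = EmotionNet(series_length=128, n_keyframes=1, seed=2)
        s = _toy_samples(2)
        before = predict_proba(net, s)
        net.save(tmp_path / "ckpt")
        back = EmotionNet.load(tmp_path / "ckpt")
        after = predict_proba(back, s)
        np.testing.assert_allclose(after, before, atol=1e-6)

    def test_predict_label(self):
        net = EmotionNet(series_length=128, n_keyframes=1, seed=0)
        probs, label = predict(net, _toy_samples(1)[0])
        assert label in EMOTIONS
        assert probs.shape == (4,)

    def test_sample_validation(self):
        with pytest.raises(ValueError):
            EmotionSample(respiration=np.zeros(10), heartbeat=np.zeros(11),
                          keyframes=np.zeros((1, 227, 227, 3)), label="happy")
        with pytest.raises(ValueError):
            EmotionSample(respiration=np.zeros(10), heartbeat=np.zeros(10),
                          keyframes=np.zeros((1, 64, 64, 3)), label="happy")
        with pytest.raises(ValueError):
            EmotionSample(respiration=np.zeros(10), heartbeat=np.zeros(10),
                          keyframes=np.zeros((1, 227, 227, 3)), label="bored")


class TestTraining:
    def test_arrays_normalized(self):
        resp, heart, faces, labels = samples_to_arrays(_toy_samples(4))
        np.testing.assert_allclose(resp.mean(axis=1), 0.0, atol=1e-5)
        np.testing.assert_allclose(resp.std(axis=1), 1.0, rtol=1e-4)
        assert faces.min() >= -0.5 and faces.max() <= 0.5
        np.testing.assert_array_equal(labels, [0, 1, 2, 3])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(val_fraction=1.0)

    def test_train_loss_decreases(self):
        samples = _toy_samples(8)
        cfg = TrainConfig(epochs=3, batch_size=4, learning_rate=3e-3,
                          seed=0, val_fraction=0.0)
        net, hist = train(samples, cfg)
        assert len(hist.train_loss) == 3
        assert hist.train_loss[-1] < hist.train_loss[0]
        # reproducible end-to-end
        net2, hist2 = train(samples, cfg)
        np.testing.assert_allclose(hist2.train_loss, hist.train_loss,
                                   rtol=1e-5)

    def test_history_csv(self, tmp_path):
        h = TrainHistory(epochs=[0, 1], train_loss=[1.0, 0.5],
                         val_accuracy=[0.25, 0.5])
        h.to_csv(tmp_path / "h.csv")
        text = (tmp_path / "h.csv").read_text()
        assert "epoch,loss,val_accuracy" in text

    def test_unknown_optimizer(self):
        with pytest.raises(ValueError):
            train(_toy_samples(4), TrainConfig(epochs=1, val_fraction=0.0,
                                               optimizer="sgd"))

    def test_evaluate_accuracy_range(self):
        net = EmotionNet(series_length=128, n_keyframes=1, seed=0)
        acc = evaluate_accuracy(net, _toy_samples(4))
        assert 0.0 <= acc <= 1.0
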