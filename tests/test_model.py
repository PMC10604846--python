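import numpy as np
import pytest

from gaitrec import build_joint_graph, default_joint_set
from gaitrec.errors import ConfigurationError, ValidationError
from gaitrec.model import (
    EncoderOutputs,
    HybridModel,
    HybridModelConfig,
    TrainOptions,
    loss,
    train_model,
)


TINY = dict(stgcn_channels=(4, 6), stgcn_strides=(1, 2), stgcn_out=8,
            lstm_hidden=6, lstm_layers=2, lstm_out=4, ann_out=4,
            n_params=26, n_angles=25, dropout=0.0)


@pytest.fixture(scope="module")
def tiny_model():
    return HybridModel(HybridModelConfig(n_classes=4, seed=3, **TINY))


@pytest.fixture(scope="module")
def table_model():
    """Full reference-plan model (Table-style channel configuration)."""
    return HybridModel(HybridModelConfig(n_classes=6, seed=0))


def _views(rng, b=3, t=30, n_angles=25, n_params=26):
    return {
        "skeleton": rng.normal(size=(b, 3, t, 19)),
        "angles": rng.normal(size=(b, t, n_angles)),
        "params": rng.normal(size=(b, n_params)),
    }


class TestConfig:
    def test_default_matches_reference_plan(self):
        cfg = HybridModelConfig(n_classes=6)
        assert cfg.stgcn_channels == (64, 64, 64, 64, 128, 128, 128, 256, 256,
                                      256)
        assert cfg.temporal_kernel == 9
        assert cfg.stgcn_out == 64
        assert cfg.lstm_hidden == 128 and cfg.lstm_layers == 4
        assert cfg.lstm_out == 16 and cfg.ann_out == 16
        assert cfg.dropout == 0.5
        assert cfg.fusion_dim == 96

    def test_no_branches_rejected(self):
        with pytest.raises(ConfigurationError):
            HybridModelConfig(n_classes=3, branches=())

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            HybridModelConfig(n_classes=1)

    def test_negative_l2_rejected(self):
        with pytest.raises(ConfigurationError):
            HybridModelConfig(n_classes=3, l2=-0.1)


class TestEncoders:
    def test_full_plan_output_dimensions(self, table_model):
        """Reference plan: f_S 64, f_A 16, f_P 16 for a (3, 100, N) input."""
        rng = np.random.default_rng(0)
        f_s = table_model.stgcn_encode(rng.normal(size=(3, 100, 19)))
        assert f_s.shape == (64,)
        f_a = table_model.lstm_encode(rng.normal(size=(40, 25)))
        assert f_a.shape == (16,)
        f_p = table_model.ann_encode(rng.normal(size=26))
        assert f_p.shape == (16,)

    def test_full_plan_training_step_runs(self, table_model):
        """One optimizer step through the complete reference architecture."""
        rng = np.random.default_rng(6)
        views = _views(rng, b=2, t=50)
        labels = np.array([0, 3])
        loss1, _ = table_model.loss_and_grad(views, labels)
        assert np.isfinite(loss1)
        assert any(np.abs(p.grad).max() > 0 for p in table_model.params)

    def test_lstm_output_length_for_any_t(self, tiny_model):
        rng = np.random.default_rng(1)
        for t in (1, 7, 50):
            out = tiny_model.lstm_encode(rng.normal(size=(t, 25)))
            assert out.shape == (4,)

    def test_ann_zero_weights_gives_relu_bias(self, tiny_model):
        saved = tiny_model.ann_fc.W.value.copy()
        saved_b = tiny_model.ann_fc.b.value.copy()
        tiny_model.ann_fc.W.value[...] = 0.0
        tiny_model.ann_fc.b.value[...] = np.array([1.0, -2.0, 0.5, -0.1])
        out = tiny_model.ann_encode(np.ones(26))
        np.testing.assert_allclose(out, [1.0, 0.0, 0.5, 0.0], atol=1e-12)
        tiny_model.ann_fc.W.value[...] = saved
        tiny_model.ann_fc.b.value[...] = saved_b

    def test_ann_output_nonnegative(self, tiny_model):
        rng = np.random.default_rng(2)
        for _ in range(10):
            out = tiny_model.ann_encode(rng.normal(size=26) * 10)
            assert out.min() >= 0.0

    def test_ann_hand_affine_case(self):
        cfg = HybridModelConfig(n_classes=2, branches=("params",), ann_out=2,
                                n_params=2, seed=0)
        m = HybridModel(cfg)
        m.ann_fc.W.value[...] = [[1.0, -1.0], [2.0, 0.5]]
        m.ann_fc.b.value[...] = [0.1, 0.2]
        out = m.ann_encode(np.array([1.0, 2.0]))
        np.testing.assert_allclose(out, np.maximum(
            [1 * 1 + 2 * 2 + 0.1, -1 + 1.0 + 0.2], 0), atol=1e-12)

    def test_wrong_angle_count_rejected(self, tiny_model):
        with pytest.raises(ValidationError, match="angle"):
            tiny_model.lstm_encode(np.zeros((10, 7)))

    def test_wrong_param_length_rejected(self, tiny_model):
        with pytest.raises(ValidationError, match="param"):
            tiny_model.ann_encode(np.zeros(5))

    def test_too_short_sequence_reports_required_t(self, tiny_model):
        with pytest.raises(ValidationError, match="at least 9"):
            tiny_model.stgcn_encode(np.zeros((3, 4, 19)))

    def test_permutation_equivariance(self):
        """Relabeling joints consistently leaves f_S unchanged."""
        joints = default_joint_set()
        rng = np.random.default_rng(4)
        perm = rng.permutation(joints.n_joints)
        cfg = HybridModelConfig(n_classes=3, branches=("skeleton",), seed=5,
                                **{k: v for k, v in TINY.items()
                                   if k.startswith("stgcn")})
        graph = build_joint_graph(joints)
        m = HybridModel(cfg, graph)
        x = rng.normal(size=(3, 20, joints.n_joints))
        f1 = m.stgcn_encode(x)

        permuted_adj = graph.adjacency[:, perm][:, :, perm]
        m2 = HybridModel(cfg, graph)
        for blk in m2.blocks:
            blk.gcn.A = permuted_adj
        # data BN parameters are per-joint: permute them consistently
        m2.data_bn.gamma.value[...] = m.data_bn.gamma.value[perm]
        m2.data_bn.beta.value[...] = m.data_bn.beta.value[perm]
        f2 = m2.stgcn_encode(x[:, :, perm])
        np.testing.assert_allclose(f1, f2, atol=1e-5)


class TestFusionHead:
    def test_zero_head_weights_uniform_probabilities(self, tiny_model):
        saved_w = tiny_model.head_fc.W.value.copy()
        saved_b = tiny_model.head_fc.b.value.copy()
        tiny_model.head_fc.W.value[...] = 0.0
        tiny_model.head_fc.b.value[...] = 0.0
        rng = np.random.default_rng(0)
        out = EncoderOutputs(f_s=rng.random(8), f_a=rng.random(4),
                             f_p=rng.random(4))
        probs = tiny_model.fuse_and_classify(out)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)
        tiny_model.head_fc.W.value[...] = saved_w
        tiny_model.head_fc.b.value[...] = saved_b

    def test_probabilities_sum_to_one(self, tiny_model):
        rng = np.random.default_rng(1)
        for _ in range(10):
            out = EncoderOutputs(f_s=rng.normal(size=8),
                                 f_a=rng.normal(size=4),
                                 f_p=rng.normal(size=4))
            probs = tiny_model.fuse_and_classify(out)
            assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_binary_softmax_closed_form(self):
        cfg = HybridModelConfig(n_classes=2, branches=("params",), ann_out=3,
                                n_params=4, dropout=0.0, seed=0)
        m = HybridModel(cfg)
        from gaitrec.nn import softmax
        logits = np.array([1.3, -0.4])
        probs = softmax(logits)
        expected = np.exp(1.3) / (np.exp(1.3) + np.exp(-0.4))
        assert probs[0] == pytest.approx(expected, abs=1e-12)

    def test_missing_branch_output_rejected(self, tiny_model):
        with pytest.raises(ValidationError, match="missing encoder output"):
            tiny_model.fuse_and_classify(EncoderOutputs(f_s=np.zeros(8)))


class TestLossOp:
    def test_perfect_prediction_zero(self):
        assert loss(np.array([0, 1.0]), np.array([0, 1.0])) == pytest.approx(0.0)

    def test_uniform_is_ln_c(self):
        c = 6
        y = np.eye(c)[2]
        assert loss(y, np.full(c, 1 / c)) == pytest.approx(np.log(c))

    def test_l2_additivity(self):
        w = [np.array([[2.0]])]
        base = loss(np.array([1.0, 0]), np.array([0.6, 0.4]))
        reg = loss(np.array([1.0, 0]), np.array([0.6, 0.4]), 0.5, w)
        assert reg - base == pytest.approx(0.5 * 0.5 * 4.0)


class TestPredictAndTraining:
    def _toy_data(self, rng, n=40, t=20):
        """Linearly separable two-class toy set in all three views."""
        labels = rng.integers(0, 2, n)
        views = _views(rng, b=n, t=t)
        views["params"][:, 0] = labels * 4.0 - 2.0
        views["angles"][:, :, 0] += labels[:, None] * 30.0
        views["skeleton"][:, 1, :, :] += labels[:, None, None] * 0.5
        return views, labels

    def test_predict_argmax_consistency_and_determinism(self):
        rng = np.random.default_rng(7)
        cfg = HybridModelConfig(n_classes=2, seed=1, **TINY)
        m = HybridModel(cfg)
        views, labels = self._toy_data(rng, n=6)
        idx, probs = m.predict(views)
        np.testing.assert_array_equal(idx, np.argmax(probs, axis=-1))
        idx2, probs2 = m.predict(views)
        np.testing.assert_array_equal(probs, probs2)

    def test_missing_view_rejected(self, tiny_model):
        with pytest.raises(ValidationError, match="missing input view"):
            tiny_model.forward({"params": np.zeros((2, 26))})

    def test_training_loss_decreases_and_learns(self):
        rng = np.random.default_rng(8)
        views, labels = self._toy_data(rng, n=40)
        cfg = HybridModelConfig(n_classes=2, seed=2, **TINY)
        m = HybridModel(cfg)
        hist = train_model(m, views, labels,
                           opts=TrainOptions(max_epochs=25, batch_size=20,
                                             seed=3, learning_rate=1e-2))
        assert hist["train_loss"].iloc[-1] < hist["train_loss"].iloc[0]
        test_views, test_labels = self._toy_data(np.random.default_rng(99),
                                                 n=30)
        pred, _ = m.predict(test_views)
        assert np.mean(pred == test_labels) >= 0.9

    def test_identical_seed_reproduces_history_exactly(self):
        rng = np.random.default_rng(9)
        views, labels = self._toy_data(rng, n=24)
        hists = []
        for _ in range(2):
            cfg = HybridModelConfig(n_classes=2, seed=4, **TINY)
            m = HybridModel(cfg)
            hists.append(train_model(
                m, views, labels,
                opts=TrainOptions(max_epochs=6, batch_size=12, seed=5)))
        for col in ("train_loss", "train_accuracy"):
            np.testing.assert_array_equal(hists[0][col], hists[1][col])

    def test_empty_split_rejected(self, tiny_model):
        with pytest.raises(ValidationError, match="empty"):
            train_model(tiny_model, {}, np.array([], dtype=int))

    def test_early_stopping_restores_best(self):
        rng = np.random.default_rng(10)
        views, labels = self._toy_data(rng, n=30)
        val_views, val_labels = self._toy_data(np.random.default_rng(11), n=12)
        cfg = HybridModelConfig(n_classes=2, seed=6, **TINY)
        m = HybridModel(cfg)
        hist = train_model(m, views, labels, val_views, val_labels,
                           opts=TrainOptions(max_epochs=40, batch_size=15,
                                             patience=5, seed=7))
        assert "val_loss" in hist.columns
        assert len(hist) <= 40

    def test_l2_term_increases_reported_loss(self):
        rng = np.random.default_rng(12)
        views, labels = self._toy_data(rng, n=10)
        out = {}
        for lam in (0.0, 1.0):
            cfg = HybridModelConfig(n_classes=2, seed=8, l2=lam, **TINY)
            m = HybridModel(cfg)
            total, _ = m.loss_and_grad(views, labels)
            out[lam] = total
        assert out[1.0] > out[0.0]


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(13)
        cfg = HybridModelConfig(n_classes=3, seed=9, **TINY)
        m = HybridModel(cfg)
        views = _views(rng, b=4)
        _, probs = m.predict(views)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = HybridModel.load(path)
        _, probs2 = m2.predict(views)
        np.testing.assert_allclose(probs, probs2, atol=1e-12)
        assert m2.config.n_classes == 3
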