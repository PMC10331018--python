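"""Architecture contracts, attention/aggregator semantics, and oracle
equivalence of the bag classifier's building blocks."""

import numpy as np
import pytest

import modalmil as mm
from modalmil import nn
from modalmil.model import (ExtractorConfig, MILNet, bag_stream,
                            default_channels, excite, fuse_scores,
                            instance_stream, reweight, squeeze)


# ---------------------------------------------------------------------------
# feature extractor architecture
# ---------------------------------------------------------------------------

class TestExtractorArchitecture:
    def test_depth5_shapes_64(self):
        """Depth 5 at 64x64: pre-flatten 256x2x2 (1024 flat), embedding 128."""
        cfg = ExtractorConfig()
        assert cfg.resolved_channels() == (16, 32, 64, 128, 256)
        assert cfg.spatial_sides()[-1] == 2
        assert cfg.flat_dim() == 256 * 2 * 2
        net = MILNet(cfg, seed=0)
        x = np.random.default_rng(0).normal(size=(2, 1, 64, 64))
        pre, emb = net.extractor.forward_with_maps(x)
        assert pre.shape == (2, 256, 2, 2)
        assert emb.shape == (2, 128)

    def test_depth3_preflatten(self):
        cfg = ExtractorConfig(n_conv_layers=3, channels=(16, 32, 64))
        net = MILNet(cfg, seed=0)
        x = np.random.default_rng(1).normal(size=(1, 1, 64, 64))
        pre, _ = net.extractor.forward_with_maps(x)
        assert pre.shape == (1, 64, 8, 8)

    @pytest.mark.parametrize("depth,last_side", [(3, 8), (4, 4), (5, 2),
                                                 (6, 1), (7, 1)])
    def test_depth_sweep_spatial_contract(self, depth, last_side):
        """Pooling halves the side per block; depth 7 stops pooling at 1px."""
        cfg = ExtractorConfig(n_conv_layers=depth,
                              channels=default_channels(depth))
        cfg.validate()
        assert cfg.spatial_sides()[-1] == last_side
        net = MILNet(cfg, seed=0)
        x = np.random.default_rng(2).normal(size=(1, 1, 64, 64))
        pre, emb = net.extractor.forward_with_maps(x)
        assert pre.shape[2:] == (last_side, last_side)
        assert emb.shape == (1, cfg.embed_dim)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            ExtractorConfig(n_conv_layers=8, channels=(8,) * 8).validate()
        with pytest.raises(ValueError):
            ExtractorConfig(n_conv_layers=4, channels=(8, 8)).validate()

    def test_weight_sharing_identical_slices(self, tiny_extractor):
        net = MILNet(tiny_extractor, seed=1)
        sl = np.random.default_rng(3).normal(size=(16, 16))
        x = np.stack([sl, sl])[:, None]
        _, emb = net.extractor.forward_with_maps(x)
        np.testing.assert_allclose(emb[0], emb[1], atol=1e-12)


# ---------------------------------------------------------------------------
# modality attention
# ---------------------------------------------------------------------------

class TestAttention:
    def test_squeeze_constant_and_arithmetic(self):
        m = np.zeros((5, 2, 128))
        m[0] = 7.0
        m[1, 0], m[1, 1] = 1.0, 3.0
        d = squeeze(nn.Tensor(m)).value
        assert d[0] == pytest.approx(7.0)
        assert d[1] == pytest.approx(2.0)

    def test_squeeze_matches_double_loop_oracle(self, rng):
        m = rng.normal(size=(5, 4, 16))
        d = squeeze(nn.Tensor(m)).value
        for k in range(5):
            acc = 0.0
            for i in range(4):
                for j in range(16):
                    acc += m[k, i, j]
            assert d[k] == pytest.approx(acc / (4 * 16), abs=1e-6)

    def test_excite_identity_pregate(self):
        eye = nn.Tensor(np.eye(5))
        zero = nn.Tensor(np.zeros(5))
        d = nn.Tensor(np.array([0.1, 0.4, 0.2, 0.3, 0.5]))
        pre = excite(d, eye, zero, eye, zero, gate="none").value
        np.testing.assert_allclose(pre, d.value, atol=1e-12)

    def test_excite_zero_descriptor_sigmoid_half(self, rng):
        w1 = nn.Tensor(rng.normal(size=(5, 5)))
        w2 = nn.Tensor(rng.normal(size=(5, 5)))
        zero = nn.Tensor(np.zeros(5))
        a = excite(nn.Tensor(np.zeros(5)), w1, zero, w2, zero).value
        np.testing.assert_allclose(a, 0.5, atol=1e-12)

    def test_excite_matches_matrix_algebra_oracle(self, rng):
        w1 = rng.normal(size=(4, 5))
        b1 = rng.normal(size=4)
        w2 = rng.normal(size=(5, 4))
        b2 = rng.normal(size=5)
        d = rng.normal(size=5)
        a = excite(nn.Tensor(d), nn.Tensor(w1), nn.Tensor(b1),
                   nn.Tensor(w2), nn.Tensor(b2)).value
        hidden = np.maximum(w1 @ d + b1, 0.0)
        oracle = 1.0 / (1.0 + np.exp(-(w2 @ hidden + b2)))
        np.testing.assert_allclose(a, oracle, atol=1e-6)

    def test_reweight_selection_uniform_zero(self, rng):
        m = rng.normal(size=(5, 3, 8))
        one_hot = np.zeros(5)
        one_hot[2] = 1.0
        np.testing.assert_allclose(
            reweight(nn.Tensor(m), nn.Tensor(one_hot)).value, m[2], atol=1e-12)
        np.testing.assert_allclose(
            reweight(nn.Tensor(m), nn.Tensor(np.full(5, 0.2))).value,
            m.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            reweight(nn.Tensor(m), nn.Tensor(np.zeros(5))).value, 0.0)

    def test_one_hot_attention_is_single_modality_model(self, tiny_extractor, rng):
        """Selecting one modality reproduces that modality's own forward."""
        net = MILNet(tiny_extractor, seed=4)
        x = rng.normal(size=(5, 3, 16, 16))
        emb = net.extractor.forward(
            nn.Tensor(x.reshape(15, 1, 16, 16)), training=False)
        m = emb.value.reshape(5, 3, -1)
        one_hot = np.zeros(5)
        one_hot[1] = 1.0
        h = reweight(nn.Tensor(m), nn.Tensor(one_hot)).value
        np.testing.assert_allclose(h, m[1], atol=1e-12)


# ---------------------------------------------------------------------------
# dual-stream aggregator
# ---------------------------------------------------------------------------

class TestAggregator:
    def test_instance_stream_max_and_ties(self):
        h = nn.Tensor(np.diag([0.2, 0.9, 0.4]) @ np.ones((3, 3)))
        w0 = nn.Tensor(np.array([1 / 3] * 3))
        scores, c_m, idx = instance_stream(h, w0)
        np.testing.assert_allclose(scores.value, [0.2, 0.9, 0.4], atol=1e-12)
        assert float(c_m.value) == pytest.approx(0.9)
        assert idx == 1
        # duplicate max -> lowest index
        h2 = nn.Tensor(np.array([[0.9], [0.1], [0.9]]))
        _, _, idx2 = instance_stream(h2, nn.Tensor(np.array([1.0])))
        assert idx2 == 0

    def test_singleton_bag(self, rng):
        h = rng.normal(size=(1, 8))
        w0, wb = rng.normal(size=8), rng.normal(size=8)
        wq, wv = rng.normal(size=(8, 8)), rng.normal(size=(8, 8))
        scores, c_m, idx = instance_stream(nn.Tensor(h), nn.Tensor(w0))
        assert idx == 0
        assert float(c_m.value) == pytest.approx(float(h[0] @ w0))
        u, b, c_b = bag_stream(nn.Tensor(h), 0, nn.Tensor(wq), nn.Tensor(wv),
                               nn.Tensor(wb))
        np.testing.assert_allclose(u.value, [1.0])
        np.testing.assert_allclose(b.value, wv @ h[0], atol=1e-10)
        assert float(c_b.value) == pytest.approx(float(wb @ wv @ h[0]))

    def test_identical_instances_uniform_similarity(self, rng):
        h = np.tile(rng.normal(size=8), (4, 1))
        u, b, _ = bag_stream(nn.Tensor(h), 2, nn.Tensor(np.eye(8)),
                             nn.Tensor(np.eye(8)), nn.Tensor(rng.normal(size=8)))
        np.testing.assert_allclose(u.value, 0.25, atol=1e-12)
        np.testing.assert_allclose(b.value, h[0], atol=1e-10)

    def test_bag_stream_matches_double_loop_oracle(self, rng):
        """Softmax similarity and weighted sum against explicit loops."""
        for _ in range(10):
            s, e = int(rng.integers(2, 8)), 16
            h = rng.normal(size=(s, e))
            wq, wv = rng.normal(size=(e, e)), rng.normal(size=(e, e))
            wb = rng.normal(size=e)
            m_idx = int(rng.integers(s))
            u, b, c_b = bag_stream(nn.Tensor(h), m_idx, nn.Tensor(wq),
                                   nn.Tensor(wv), nn.Tensor(wb))
            q = np.array([wq @ h[i] for i in range(s)])
            q = np.array([qi / np.linalg.norm(qi) for qi in q])
            v = np.array([wv @ h[i] for i in range(s)])
            raw = np.array([np.exp(np.dot(q[i], q[m_idx])
                                   - max(np.dot(q[k], q[m_idx])
                                         for k in range(s)))
                            for i in range(s)])
            u_oracle = raw / raw.sum()
            b_oracle = sum(u_oracle[i] * v[i] for i in range(s))
            np.testing.assert_allclose(u.value, u_oracle, atol=1e-5)
            np.testing.assert_allclose(b.value, b_oracle, atol=1e-5)
            assert float(c_b.value) == pytest.approx(float(wb @ b_oracle), abs=1e-5)
            assert u.value.min() >= 0
            assert u.value.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fuse_scores(self):
        assert float(fuse_scores(nn.Tensor(0.9), nn.Tensor(0.5)).value) == \
            pytest.approx(0.7)
        assert float(fuse_scores(nn.Tensor(0.3), nn.Tensor(0.3)).value) == \
            pytest.approx(0.3)
        assert float(fuse_scores(nn.Tensor(0.0), nn.Tensor(0.0)).value) == 0.0


# ---------------------------------------------------------------------------
# whole-network properties
# ---------------------------------------------------------------------------

class TestForwardCase:
    def test_permutation_invariance(self, tiny_extractor, rng):
        net = MILNet(tiny_extractor, seed=6)
        x = rng.normal(size=(5, 4, 16, 16))
        out = net.forward_bag(x)
        perm = rng.permutation(4)
        out_p = net.forward_bag(x[:, perm])
        assert out_p.aggregation.c_final == pytest.approx(
            out.aggregation.c_final, abs=1e-10)
        np.testing.assert_allclose(out_p.aggregation.U,
                                   out.aggregation.U[perm], atol=1e-10)
        assert perm[out_p.aggregation.critical_index] == \
            out.aggregation.critical_index

    def test_eval_determinism(self, tiny_extractor, rng):
        net = MILNet(tiny_extractor, seed=7)
        x = rng.normal(size=(5, 2, 16, 16))
        a = net.forward_bag(x).aggregation.c_final
        b = net.forward_bag(x).aggregation.c_final
        assert a == b

    def test_singleton_bag_defined(self, tiny_extractor, rng):
        net = MILNet(tiny_extractor, seed=8)
        out = net.forward_bag(rng.normal(size=(5, 1, 16, 16)))
        assert np.isfinite(out.aggregation.c_final)
        assert 0.0 < out.probability < 1.0

    def test_final_score_is_stream_mean(self, tiny_extractor, rng):
        net = MILNet(tiny_extractor, seed=9)
        agg = net.forward_bag(rng.normal(size=(5, 3, 16, 16))).aggregation
        assert agg.c_final == pytest.approx((agg.c_m + agg.c_b) / 2, abs=1e-12)
        assert agg.c_m == pytest.approx(agg.instance_scores.max(), abs=1e-12)

    def test_ablation_architecture_introspection(self, tiny_extractor):
        """Disabled modules contribute no parameters; fusion reduces correctly."""
        full = MILNet(tiny_extractor, seed=1)
        bare = MILNet(tiny_extractor, use_attention=False,
                      use_aggregator=False, seed=1)
        assert not hasattr(bare, "att_w1") and not hasattr(bare, "wq")
        n_extract = len(bare.extractor.parameters())
        assert len(bare.parameters()) == n_extract + 1  # only W0 extra
        assert len(full.parameters()) == n_extract + 1 + 4 + 3
        x = np.random.default_rng(0).normal(size=(5, 3, 16, 16))
        out = bare.forward_bag(x)
        np.testing.assert_allclose(out.attention.a, 0.2, atol=1e-12)
        assert out.aggregation.c_final == pytest.approx(
            out.aggregation.instance_scores.mean(), abs=1e-12)
        np.testing.assert_allclose(out.aggregation.U, 1 / 3, atol=1e-12)

    def test_checkpoint_roundtrip(self, tiny_extractor, tmp_path, rng):
        net = MILNet(tiny_extractor, seed=11)
        x = rng.normal(size=(5, 2, 16, 16))
        before = net.forward_bag(x).aggregation.c_final
        path = tmp_path / "ckpt.zip"
        net.save(path)
        restored = MILNet.load(path)
        assert restored.forward_bag(x).aggregation.c_final == \
            pytest.approx(before, abs=1e-12)

    def test_checkpoint_architecture_mismatch(self, tiny_extractor, tmp_path):
        net = MILNet(tiny_extractor, seed=1)
        path = tmp_path / "ckpt.zip"
        net.save(path)
        other = MILNet(ExtractorConfig(n_conv_layers=3, channels=(8, 8, 8),
                                       embed_dim=16, input_size=16), seed=1)
        with pytest.raises(ValueError, match="mismatch"):
            other.set_state(net.get_state())

    def test_wrong_modality_count_rejected(self, tiny_extractor, rng):
        net = MILNet(tiny_extractor, seed=1)
        with pytest.raises(ValueError, match="modalities"):
            net.forward_bag(rng.normal(size=(4, 2, 16, 16)))
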