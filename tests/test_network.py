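"""SE primitives, lateral fusion, dual-pathway forward contracts, training."""

import numpy as np
import pytest

from sefast._autograd import Tensor
from sefast.network import (
    NetConfig,
    SEFastNet,
    lateral_fuse,
    se_excite,
    se_scale,
    se_squeeze,
)

RNG = np.random.default_rng(7)


class TestNetConfig:
    def test_reference_arithmetic(self):
        cfg = NetConfig.resnet50_3d()
        assert cfg.n_slow == 4
        assert cfg.n_fast == 32
        assert cfg.c_fast == 8
        assert cfg.alpha == 8

    @pytest.mark.parametrize(
        "kw",
        [
            dict(window_len=60),  # not divisible by s_slow=16
            dict(c_slow=12),  # beta·C not integral
            dict(se_placement="middle"),
            dict(s_slow=15),  # not a multiple of s_fast
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            NetConfig.tiny(**kw)


class TestSEPrimitives:
    def test_squeeze_constant_map(self):
        u = np.full((3, 2, 4, 4), 3.5)
        assert se_squeeze(u) == pytest.approx([3.5, 3.5, 3.5])

    def test_squeeze_signed_channels(self):
        u = np.stack([np.ones((2, 3, 3)), -np.ones((2, 3, 3))])
        assert se_squeeze(u) == pytest.approx([1.0, -1.0])

    def test_squeeze_matches_bruteforce_mean(self):
        u = RNG.normal(size=(2, 2, 2, 2))
        expected = [u[c].sum() / u[c].size for c in range(2)]
        assert se_squeeze(u) == pytest.approx(expected)

    def test_excite_zero_vector_gives_half(self):
        w1 = RNG.normal(size=(2, 4))
        w2 = RNG.normal(size=(4, 2))
        assert se_excite(np.zeros(4), w1, w2) == pytest.approx([0.5] * 4)

    def test_excite_hand_computed(self):
        # C=2, ratio 1: W1=[1,1], W2=[[1],[1]], z=(1,1) -> hidden=relu(2)=2,
        # s = (sigmoid(2), sigmoid(2))
        s = se_excite(np.array([1.0, 1.0]), np.array([[1.0, 1.0]]),
                      np.array([[1.0], [1.0]]))
        assert s == pytest.approx([1 / (1 + np.exp(-2.0))] * 2)

    def test_excite_relu_kills_negative_hidden(self):
        s = se_excite(np.array([-1.0, -1.0]), np.array([[1.0, 1.0]]),
                      np.array([[1.0], [1.0]]))
        assert s == pytest.approx([0.5, 0.5])

    def test_excite_shape_mismatch(self):
        with pytest.raises(ValueError):
            se_excite(np.zeros(4), np.zeros((2, 3)), np.zeros((4, 2)))

    def test_scale_identity_zero_and_elementwise(self):
        u = RNG.normal(size=(2, 3, 4, 4))
        assert np.array_equal(se_scale(u, np.ones(2)), u)
        assert not se_scale(u, np.zeros(2)).any()
        scaled = se_scale(u, np.array([0.5, 2.0]))
        for c, s in enumerate([0.5, 2.0]):
            assert np.allclose(scaled[c], s * u[c])
        with pytest.raises(ValueError):
            se_scale(u, np.ones(3))


class TestLateralFuse:
    def test_shape_algebra(self):
        """Slow T=4 + fast T=32 fuse to T=4 with C_slow + 2·C_fast channels."""
        c_slow, c_fast = 16, 2
        slow = RNG.normal(size=(1, c_slow, 4, 5, 5)).astype(np.float32)
        fast = RNG.normal(size=(1, c_fast, 32, 5, 5)).astype(np.float32)
        w = RNG.normal(size=(2 * c_fast, c_fast, 5, 1, 1)).astype(np.float32)
        fused = lateral_fuse(fast, slow, w, alpha=8)
        assert fused.shape == (1, c_slow + 2 * c_fast, 4, 5, 5)

    def test_zero_fast_features_leave_slow_channels_unchanged(self):
        slow = RNG.normal(size=(2, 4, 4, 3, 3)).astype(np.float32)
        fast = np.zeros((2, 2, 32, 3, 3), dtype=np.float32)
        w = RNG.normal(size=(4, 2, 5, 1, 1)).astype(np.float32)
        fused = lateral_fuse(fast, slow, w, alpha=8)
        assert np.array_equal(fused.data[:, :4], slow)
        assert not fused.data[:, 4:].any()

    def test_incompatible_shapes_rejected(self):
        slow = np.zeros((1, 4, 4, 3, 3), dtype=np.float32)
        w = np.zeros((4, 2, 5, 1, 1), dtype=np.float32)
        with pytest.raises(ValueError, match="spatial"):
            lateral_fuse(np.zeros((1, 2, 32, 5, 5), dtype=np.float32), slow, w)
        with pytest.raises(ValueError, match="temporal"):
            lateral_fuse(np.zeros((1, 2, 16, 3, 3), dtype=np.float32), slow, w)


def _random_clips(batch=2, t_fast=32, hw=(18, 32), seed=0):
    rng = np.random.default_rng(seed)
    fast = rng.normal(size=(batch, 3, t_fast, *hw)).astype(np.float32)
    slow = np.ascontiguousarray(fast[:, :, ::8])
    return slow, fast


class TestForward:
    def test_output_shape_one_logit_row_per_box(self):
        net = SEFastNet(NetConfig.tiny(), seed=0)
        slow, fast = _random_clips()
        rois = [(0, 0.2, 0.2, 0.8, 0.8), (1, 0.1, 0.1, 0.5, 0.5)]
        logits = net.forward(slow, fast, rois)
        assert logits.shape == (2, 5)

    def test_duplicated_box_duplicates_logit_row(self):
        net = SEFastNet(NetConfig.tiny(), seed=0)
        slow, fast = _random_clips()
        rois = [(0, 0.2, 0.2, 0.8, 0.8), (0, 0.2, 0.2, 0.8, 0.8)]
        logits = net.forward(slow, fast, rois).data
        assert np.array_equal(logits[0], logits[1])

    def test_empty_box_list_rejected(self):
        net = SEFastNet(NetConfig.tiny(), seed=0)
        slow, fast = _random_clips()
        with pytest.raises(ValueError, match="box"):
            net.forward(slow, fast, [])

    def test_all_lateral_connections_touched_once(self):
        net = SEFastNet(NetConfig.tiny(), seed=0)
        slow, fast = _random_clips()
        net.forward(slow, fast, [(0, 0.2, 0.2, 0.8, 0.8)])
        assert net.lateral_calls == net.cfg.lateral_connection_count == 4

    @pytest.mark.parametrize("placement", ["front", "end"])
    def test_unit_excitation_is_a_noop(self, placement):
        """Forcing s=1 must reproduce the attention-free network bitwise."""
        cfg_se = NetConfig.tiny(se_placement=placement)
        net_se = SEFastNet(cfg_se, seed=3)
        net_plain = SEFastNet(NetConfig.tiny(se_placement="none"), seed=3)
        for key in net_plain.params:
            net_plain.params[key].data = net_se.params[key].data.copy()
        slow, fast = _random_clips(seed=4)
        rois = [(0, 0.3, 0.3, 0.7, 0.7), (1, 0.2, 0.1, 0.9, 0.8)]
        forced = net_se.forward(slow, fast, rois, force_unit_excitation=True).data
        plain = net_plain.forward(slow, fast, rois).data
        assert np.array_equal(forced, plain)

    def test_determinism(self):
        slow, fast = _random_clips(seed=9)
        rois = [(0, 0.2, 0.2, 0.8, 0.8)]
        a = SEFastNet(NetConfig.tiny(), seed=1).forward(slow, fast, rois).data
        b = SEFastNet(NetConfig.tiny(), seed=1).forward(slow, fast, rois).data
        assert np.array_equal(a, b)

    def test_gradient_reaches_every_parameter_group(self):
        net = SEFastNet(NetConfig.tiny(se_placement="end"), seed=2)
        slow, fast = _random_clips(seed=5)
        logits = net.forward(slow, fast, [(0, 0.2, 0.2, 0.8, 0.8),
                                          (1, 0.1, 0.2, 0.7, 0.9)])
        (logits * logits).mean().backward()
        groups = {}
        for key, p in net.params.items():
            group = key.split(".")[0]
            g = 0.0 if p.grad is None else float(np.abs(p.grad).max())
            groups[group] = max(groups.get(group, 0.0), g)
        assert all(v > 0 for v in groups.values()), groups

    def test_resnet50_3d_forward_smoke(self):
        cfg = NetConfig.resnet50_3d(input_hw=(32, 32))
        net = SEFastNet(cfg, seed=0)
        slow, fast = _random_clips(batch=1, hw=(32, 32))
        logits = net.forward(slow, fast, [(0, 0.2, 0.2, 0.8, 0.8)])
        assert logits.shape == (1, 5)
        assert net.lateral_calls == 4
        assert np.all(np.isfinite(logits.data))


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        net = SEFastNet(NetConfig.tiny(), seed=11)
        path = tmp_path / "model.npz"
        net.save(path)
        loaded = SEFastNet.load(path)
        assert loaded.cfg == net.cfg
        slow, fast = _random_clips(seed=12)
        rois = [(0, 0.2, 0.2, 0.8, 0.8)]
        assert np.array_equal(net.forward(slow, fast, rois).data,
                              loaded.forward(slow, fast, rois).data)


class TestTrainedRecognition:
    def test_macro_posture_recall_on_heldout_synthetic(self, comparison_runs, labels):
        """The trained tiny network separates the three postures on held-out
        synthetic data: median macro posture recall ≥ 0.8 over 3 seeds."""
        recalls = [run["summary"].macro_posture_recall(labels)
                   for run in comparison_runs["cw_f"]]
        assert float(np.median(recalls)) >= 0.8
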