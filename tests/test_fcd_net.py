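import math

import numpy as np
import pytest

from idolseg._autograd import Tensor
from idolseg.fcd_net import (
    LossConfig,
    NetConfig,
    build_network,
    composite_loss,
    load_checkpoint,
    loss_from_logits_tensor,
    save_checkpoint,
)


def naive_composite_loss(p_fg, y, cfg: LossConfig) -> float:
    """Independent voxel-by-voxel summation oracle for the composite loss."""
    floor = 1e-7
    n = p_fg.size
    ce = dce_extra = 0.0
    inter = psum = ysum = 0.0
    for pv, yv in zip(p_fg.ravel(), y.ravel()):
        p_true = pv if yv else 1.0 - pv
        p_wrong = 1.0 - p_true
        ce += -math.log(max(p_true, floor))
        dce_extra += -math.log(max(1.0 - p_wrong, floor))
        inter += pv * yv
        psum += pv
        ysum += yv
    ce /= n
    dce = ce + cfg.dce_lambda * dce_extra / n
    soft_dice = (2 * inter + cfg.smooth) / (psum + ysum + cfg.smooth)
    return cfg.w_ce * ce + cfg.w_dce * dce + cfg.w_dice * (1 - soft_dice)


class TestCompositeLoss:
    def test_perfect_prediction_is_zero_up_to_smoothing(self):
        y = np.zeros((4, 4, 2), np.float32)
        y[1:3, 1:3, :] = 1
        loss = composite_loss(y.astype(np.float64), y, LossConfig(smooth=0.0))
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_gives_log2_cross_entropy(self):
        y = (np.random.default_rng(0).random((4, 4, 2)) < 0.5).astype(np.float32)
        cfg = LossConfig(w_ce=1, w_dce=0, w_dice=0)
        loss = composite_loss(np.full_like(y, 0.5, dtype=np.float64), y, cfg)
        assert loss == pytest.approx(math.log(2), abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.01, 0.99, (4, 4, 4)).astype(np.float32)
        y = (rng.random((4, 4, 4)) < 0.4).astype(np.float32)
        cfg = LossConfig(w_ce=1.0, w_dce=0.7, w_dice=1.3, dce_lambda=0.5, smooth=1.0)
        assert composite_loss(p, y, cfg) == pytest.approx(
            naive_composite_loss(p, y, cfg), abs=1e-5
        )

    def test_logits_route_agrees_with_probability_route(self, rng):
        logits = rng.normal(size=(2, 4, 4, 2)).astype(np.float32)
        y = (rng.random((4, 4, 2)) < 0.5).astype(np.float32)
        cfg = LossConfig()
        via_logits = loss_from_logits_tensor(Tensor(logits), y, cfg).item()
        e = np.exp(logits - logits.max(axis=0))
        p_fg = (e / e.sum(axis=0))[1]
        assert via_logits == pytest.approx(composite_loss(p_fg, y, cfg), abs=1e-5)

    def test_confident_wrong_prediction_stays_finite(self):
        y = np.ones((3, 3, 2), np.float32)
        loss = composite_loss(np.zeros_like(y, dtype=np.float64), y, LossConfig())
        assert np.isfinite(loss) and loss > 10

    def test_loss_nonnegative_random(self, rng):
        for _ in range(20):
            p = rng.random((3, 3, 3))
            y = (rng.random((3, 3, 3)) < 0.5).astype(np.float32)
            assert composite_loss(p, y, LossConfig()) >= 0

    def test_all_weights_zero_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            LossConfig(w_ce=0, w_dce=0, w_dice=0)


class TestNetwork:
    def test_output_is_probability_field_of_input_shape(self, tiny_net_cfg, rng):
        model = build_network(tiny_net_cfg, seed=0)
        x = rng.normal(size=(8, 8, 4)).astype(np.float32)
        p = model.forward_prob(x).data
        assert p.shape == (2, 8, 8, 4)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-5)
        assert (p >= 0).all()

    def test_build_is_deterministic(self, tiny_net_cfg, rng):
        a = build_network(tiny_net_cfg, seed=3)
        b = build_network(tiny_net_cfg, seed=3)
        assert a.n_parameters() == b.n_parameters()
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        x = rng.normal(size=(8, 8, 4)).astype(np.float32)
        np.testing.assert_array_equal(a.predict_prob(x), b.predict_prob(x))

    def test_down_path_width_recurrence(self):
        """Each encoder block widens its input by layers x growth_rate."""
        cfg = NetConfig(dense_block_layers=(2, 3, 4, 5, 7), growth_rate=12)
        w = cfg.first_conv_channels
        expected = []
        for n in (2, 3, 4, 5):
            w = w + n * 12
            expected.append(w)
        assert cfg.down_widths() == expected == [72, 108, 156, 216]
        model = build_network(cfg, seed=0)
        assert [db.out_channels for db in model.down_blocks] == expected

    def test_fully_convolutional_across_sizes(self, tiny_net_cfg, rng):
        model = build_network(tiny_net_cfg, seed=0)
        for shape in [(8, 8, 4), (12, 10, 6), (16, 8, 3)]:
            p = model.forward_prob(rng.normal(size=shape).astype(np.float32)).data
            assert p.shape == (2, *shape)

    def test_indivisible_inplane_shape_names_divisor(self, tiny_net_cfg, rng):
        model = build_network(tiny_net_cfg, seed=0)  # one TD stage: divisor 2
        with pytest.raises(ValueError, match="divisible by 2"):
            model.forward_prob(rng.normal(size=(7, 8, 4)).astype(np.float32))

    def test_checkpoint_roundtrip(self, tiny_net_cfg, tmp_path, rng):
        model = build_network(tiny_net_cfg, seed=5)
        path = str(tmp_path / "m.npz")
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.cfg == model.cfg
        x = rng.normal(size=(8, 8, 4)).astype(np.float32)
        np.testing.assert_array_equal(loaded.predict_prob(x), model.predict_prob(x))

    def test_copy_is_independent(self, tiny_net_cfg):
        model = build_network(tiny_net_cfg, seed=1)
        clone = model.copy()
        clone.parameters()[0].data += 1.0
        assert not np.array_equal(clone.parameters()[0].data, model.parameters()[0].data)
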