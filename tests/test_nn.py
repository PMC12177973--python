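"""Gradient and shape checks for the numpy network core."""

import numpy as np
import pytest

from slideprep.marker import LossConfig, _total_loss_with_grad
from slideprep.nn import Adam, NetConfig, SegNet
from slideprep.nn.layers import Conv2d, ConvTranspose2d, InstanceNorm


def numerical_grad(f, p, idx, eps=1e-3):
    old = p[idx]
    p[idx] = old + eps
    f1 = f()
    p[idx] = old - eps
    f2 = f()
    p[idx] = old
    return (f1 - f2) / (2 * eps)


class TestLayerGradients:
    def test_conv_weight_and_input_gradients(self, rng):
        x = rng.standard_normal((2, 3, 8, 8)).astype(np.float32)
        conv = Conv2d(3, 4, 4, 2, 1, rng)
        tgt = rng.standard_normal((2, 4, 4, 4)).astype(np.float32)

        def loss():
            return float(((conv.forward(x) - tgt) ** 2).sum())

        y = conv.forward(x, train=True)
        conv.gW[...] = 0
        dx = conv.backward(2 * (y - tgt))
        for idx in [(0, 0, 0, 0), (3, 2, 1, 3), (1, 1, 2, 2)]:
            assert conv.gW[idx] == pytest.approx(
                numerical_grad(loss, conv.W, idx), rel=2e-2, abs=1e-4)
        for idx in [(0, 0, 0, 0), (1, 2, 7, 7), (0, 1, 3, 4)]:
            assert dx[idx] == pytest.approx(
                numerical_grad(loss, x, idx), rel=2e-2, abs=1e-4)

    def test_transposed_conv_gradients_and_shape(self, rng):
        ct = ConvTranspose2d(3, 4, 4, 2, 1, rng)
        x = rng.standard_normal((2, 3, 4, 4)).astype(np.float32)
        y = ct.forward(x)
        assert y.shape == (2, 4, 8, 8)  # exact doubling
        tgt = rng.standard_normal(y.shape).astype(np.float32)

        def loss():
            return float(((ct.forward(x) - tgt) ** 2).sum())

        y = ct.forward(x, train=True)
        ct.gW[...] = 0
        dx = ct.backward(2 * (y - tgt))
        for idx in [(0, 0, 0, 0), (2, 3, 1, 2)]:
            assert ct.gW[idx] == pytest.approx(
                numerical_grad(loss, ct.W, idx), rel=2e-2, abs=1e-4)
        for idx in [(0, 0, 0, 0), (1, 2, 3, 3)]:
            assert dx[idx] == pytest.approx(
                numerical_grad(loss, x, idx), rel=2e-2, abs=1e-4)

    def test_instance_norm_gradient(self, rng):
        x = rng.standard_normal((1, 2, 5, 5)).astype(np.float32)
        innorm = InstanceNorm()
        tgt = rng.standard_normal(x.shape).astype(np.float32)

        def loss():
            return float(((innorm.forward(x) - tgt) ** 2).sum())

        y = innorm.forward(x, train=True)
        dx = innorm.backward(2 * (y - tgt))
        for idx in [(0, 0, 1, 1), (0, 1, 4, 0)]:
            assert dx[idx] == pytest.approx(
                numerical_grad(loss, x, idx), rel=3e-2, abs=2e-3)

    def test_whole_network_gradient_matches_finite_differences(self, rng):
        cfg = NetConfig(encoder_widths=(4, 5, 6, 7), decoder_widths=(6, 5, 4, 3),
                        dropout=0.0, seed=1)
        net = SegNet(cfg)
        x = rng.random((1, 3, 16, 16)).astype(np.float32)
        t = (rng.random((1, 1, 16, 16)) > 0.7).astype(np.float32)
        lcfg = LossConfig()

        def full_loss():
            return _total_loss_with_grad(net.forward(x), t, lcfg)[0]

        prob = net.forward(x, train=True)
        _, g = _total_loss_with_grad(prob, t, lcfg)
        net.zero_grad()
        net.backward(g)
        params = net.params()
        checked = 0
        for pi in (0, 8, 20, len(params) - 1):
            par, grad = params[pi]
            idx = np.unravel_index(int(np.argmax(np.abs(grad))), grad.shape)
            if abs(grad[idx]) < 1e-6:
                continue  # bias into instance norm: analytically zero
            num = numerical_grad(full_loss, par, idx, eps=3e-3)
            assert grad[idx] == pytest.approx(num, rel=5e-2, abs=1e-5)
            checked += 1
        assert checked >= 3


class TestNetworkContracts:
    def test_output_shape_matches_input_for_div16_sizes(self, rng):
        net = SegNet(NetConfig(encoder_widths=(4, 4, 4, 4),
                               decoder_widths=(4, 4, 4, 4), seed=0))
        for size in (32, 48, 80):
            x = rng.random((1, 3, size, size)).astype(np.float32)
            assert net.forward(x).shape == (1, 1, size, size)

    def test_non_divisible_input_padded_and_cropped(self, rng):
        net = SegNet(NetConfig(encoder_widths=(4, 4, 4, 4),
                               decoder_widths=(4, 4, 4, 4), seed=0))
        x = rng.random((1, 3, 50, 70)).astype(np.float32)
        assert net.forward(x).shape == (1, 1, 50, 70)

    def test_zero_weight_network_outputs_half(self, rng):
        net = SegNet(NetConfig(encoder_widths=(4, 4, 4, 4),
                               decoder_widths=(4, 4, 4, 4), seed=0))
        for p, _ in net.params():
            p[...] = 0
        out = net.forward(rng.random((1, 3, 32, 32)).astype(np.float32))
        np.testing.assert_array_equal(out, 0.5)

    def test_default_channel_widths(self):
        cfg = NetConfig()
        assert cfg.encoder_widths == (32, 64, 128, 256)
        assert cfg.decoder_widths == (128, 64, 32, 16)
        assert cfg.prehead_channels == 19
        net = SegNet(cfg)
        assert net.enc1_down.W.shape[0] == 32
        assert net.enc4_down.W.shape[0] == 256
        assert net.dec4_up.W.shape[1] == 16
        assert net.head.W.shape == (1, 19, 4, 4)

    def test_adam_converges_on_quadratic(self):
        p = np.array([5.0], dtype=np.float32)
        g = np.zeros_like(p)
        opt = Adam([(p, g)], lr=0.1)
        for _ in range(500):
            g[...] = 2 * p
            opt.step()
        assert abs(p[0]) < 1e-2

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = NetConfig(encoder_widths=(4, 4, 4, 4), decoder_widths=(4, 4, 4, 4),
                        seed=3)
        net = SegNet(cfg)
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        before = net.forward(x)
        net.save(tmp_path / "ck.npz", extra={"note": "test"})
        net2, extra = SegNet.load(tmp_path / "ck.npz")
        assert extra["note"] == "test"
        np.testing.assert_array_equal(net2.forward(x), before)
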