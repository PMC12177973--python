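"""The customized encoder-decoder segmentation network.

A U-Net-style architecture tuned for small, globally distributed circular
structures: the first and last blocks carry extra 3x3 refinement
convolutions and skip no dropout (preserving fine detail), the deepest
block and a two-layer bottleneck widen the receptive field (capturing the
global square-frame shape prior), skip connections are *additive* (the
enc3 skip through a learned 1x1 projection), and the final decoder output
(16 learned channels by default) is concatenated with the 3 input channels
before a learnable 4x4 head produces the per-pixel probability map.

With the default widths the channel progression is 3 -> 32 -> 64 -> 128 ->
256 in the encoder and 256 -> 128 -> 64 -> 32 -> 16 in the decoder, giving
a 19-channel full-resolution feature map ahead of the sigmoid head.

Spatial contract: every encoder block halves H and W, every decoder block
doubles them, so inputs must have dims divisible by 16; callers that do
not are reflect-padded and cropped back transparently.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from slideprep.nn.layers import (Conv2d, ConvTranspose2d, Dropout,
                                 InstanceNorm, ReLU, Sigmoid, F32)

logger = logging.getLogger(__name__)

_DOWN = 16  # four halvings


@dataclass
class NetConfig:
    """Architecture hyper-parameters.

    Defaults are the marker-detection network; the tissue detector reuses
    the same block structure with shallower widths.
    """

    encoder_widths: tuple = (32, 64, 128, 256)
    decoder_widths: tuple = (128, 64, 32, 16)
    in_channels: int = 3
    down_kernel: int = 4       # 4x4 stride-2 in every down/up sampling conv
    refine_kernel: int = 3     # 3x3 stride-1 refinement convolutions
    head_kernel: int = 4       # 4x4 stride-1 learnable output head
    dropout: float = 0.5
    seed: int = 0

    @property
    def prehead_channels(self) -> int:
        return self.decoder_widths[3] + self.in_channels

    def dump(self) -> dict:
        d = asdict(self)
        d["encoder_widths"] = list(self.encoder_widths)
        d["decoder_widths"] = list(self.decoder_widths)
        d["prehead_channels"] = self.prehead_channels
        return d


class SegNet:
    """Encoder-decoder segmentation network (see module docstring)."""

    def __init__(self, config: NetConfig | None = None):
        self.config = cfg = config or NetConfig()
        rng = np.random.default_rng(cfg.seed)
        self.dropout_rng = np.random.default_rng(cfg.seed + 1)
        e1, e2, e3, e4 = cfg.encoder_widths
        d1, d2, d3, d4 = cfg.decoder_widths
        dk, rk = cfg.down_kernel, cfg.refine_kernel
        dr = cfg.dropout
        drng = self.dropout_rng

        # encoder block 1: extra refinement conv, no norm, no dropout
        self.enc1_down = Conv2d(cfg.in_channels, e1, dk, 2, 1, rng)
        self.enc1_refine = Conv2d(e1, e1, rk, 1, 1, rng)
        self.enc1_relu = ReLU()
        # encoder blocks 2/3: plain down conv -> IN -> ReLU -> dropout
        self.enc2_down = Conv2d(e1, e2, dk, 2, 1, rng)
        self.enc2_norm, self.enc2_relu = InstanceNorm(), ReLU()
        self.enc2_drop = Dropout(dr, drng)
        self.enc3_down = Conv2d(e2, e3, dk, 2, 1, rng)
        self.enc3_norm, self.enc3_relu = InstanceNorm(), ReLU()
        self.enc3_drop = Dropout(dr, drng)
        # encoder block 4: extra refinement conv at the deepest scale
        self.enc4_down = Conv2d(e3, e4, dk, 2, 1, rng)
        self.enc4_refine = Conv2d(e4, e4, rk, 1, 1, rng)
        self.enc4_norm, self.enc4_relu = InstanceNorm(), ReLU()
        self.enc4_drop = Dropout(dr, drng)
        # two-layer bottleneck widening the receptive field
        self.bottleneck1 = Conv2d(e4, e4, rk, 1, 1, rng)
        self.bottleneck2 = Conv2d(e4, e4, rk, 1, 1, rng)
        # decoder block 1: deconv -> refine conv -> IN/ReLU/dropout,
        # additive skip with 1x1-projected enc3 features
        self.dec1_up = ConvTranspose2d(e4, d1, dk, 2, 1, rng)
        self.dec1_refine = Conv2d(d1, d1, rk, 1, 1, rng)
        self.dec1_norm, self.dec1_relu = InstanceNorm(), ReLU()
        self.dec1_drop = Dropout(dr, drng)
        self.skip1_proj = Conv2d(e3, d1, 1, 1, 0, rng)
        # decoder block 2: deconv -> IN/ReLU/dropout, additive skip enc2
        self.dec2_up = ConvTranspose2d(d1, d2, dk, 2, 1, rng)
        self.dec2_norm, self.dec2_relu = InstanceNorm(), ReLU()
        self.dec2_drop = Dropout(dr, drng)
        # decoder block 3: deconv -> IN/ReLU (no dropout), additive skip enc1
        self.dec3_up = ConvTranspose2d(d2, d3, dk, 2, 1, rng)
        self.dec3_norm, self.dec3_relu = InstanceNorm(), ReLU()
        # decoder block 4: deconv -> refine conv -> IN/ReLU, then the input
        # image is attached by channel concatenation (16 + 3 = 19 channels)
        self.dec4_up = ConvTranspose2d(d3, d4, dk, 2, 1, rng)
        self.dec4_refine = Conv2d(d4, d4, rk, 1, 1, rng)
        self.dec4_norm, self.dec4_relu = InstanceNorm(), ReLU()
        # learnable head: 4x4 stride-1 same-padded conv + sigmoid
        self.head = Conv2d(self.config.prehead_channels, 1, cfg.head_kernel,
                           1, (1, 2, 1, 2), rng)
        self.head_sigmoid = Sigmoid()
        self._pad_logged = False

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for name in vars(self):
            obj = getattr(self, name)
            if hasattr(obj, "params") and callable(obj.params):
                yield name, obj

    def params(self):
        out = []
        for _, layer in self._layers():
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0

    def n_parameters(self) -> int:
        return int(sum(p.size for p, _ in self.params()))

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 3, H, W) float32 in [0, 1] -> (N, 1, H, W) probabilities."""
        x = np.ascontiguousarray(x, dtype=F32)
        n, c, h, w = x.shape
        pad_h = (-h) % _DOWN
        pad_w = (-w) % _DOWN
        if pad_h or pad_w:
            if not self._pad_logged:
                logger.warning("input dims %dx%d not divisible by %d; "
                               "reflect-padding", h, w, _DOWN)
                self._pad_logged = True
            x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)),
                       mode="reflect")
        t = train
        x1 = self.enc1_relu.forward(
            self.enc1_refine.forward(self.enc1_down.forward(x, t), t), t)
        x2 = self.enc2_drop.forward(self.enc2_relu.forward(
            self.enc2_norm.forward(self.enc2_down.forward(x1, t), t), t), t)
        x3 = self.enc3_drop.forward(self.enc3_relu.forward(
            self.enc3_norm.forward(self.enc3_down.forward(x2, t), t), t), t)
        x4 = self.enc4_drop.forward(self.enc4_relu.forward(
            self.enc4_norm.forward(self.enc4_refine.forward(
                self.enc4_down.forward(x3, t), t), t), t), t)
        y = self.bottleneck2.forward(self.bottleneck1.forward(x4, t), t)

        z1 = self.dec1_drop.forward(self.dec1_relu.forward(
            self.dec1_norm.forward(self.dec1_refine.forward(
                self.dec1_up.forward(y, t), t), t), t), t)
        z1 = z1 + self.skip1_proj.forward(x3, t)
        z2 = self.dec2_drop.forward(self.dec2_relu.forward(
            self.dec2_norm.forward(self.dec2_up.forward(z1, t), t), t), t)
        z2 = z2 + x2
        z3 = self.dec3_relu.forward(
            self.dec3_norm.forward(self.dec3_up.forward(z2, t), t), t)
        z3 = z3 + x1
        z4 = self.dec4_relu.forward(self.dec4_norm.forward(
            self.dec4_refine.forward(self.dec4_up.forward(z3, t), t), t), t)
        z4 = np.concatenate([z4, x], axis=1)
        prob = self.head_sigmoid.forward(self.head.forward(z4, t), t)
        if pad_h or pad_w:
            prob = prob[:, :, :h, :w]
            if train:
                self._pad_crop = (h, w, pad_h, pad_w)
        elif train:
            self._pad_crop = None
        return prob

    def prehead_features(self, x: np.ndarray) -> np.ndarray:
        """The full-resolution feature map entering the head (inference)."""
        keep_head = self.head.forward
        captured = {}

        def grab(z, train=False):
            captured["z"] = z
            return keep_head(z, train)

        self.head.forward = grab
        try:
            self.forward(x, train=False)
        finally:
            self.head.forward = keep_head
        return captured["z"]

    def backward(self, dprob: np.ndarray) -> None:
        """Backpropagate d(loss)/d(probability map); accumulates gradients."""
        pc = getattr(self, "_pad_crop", None)
        if pc is not None:
            h, w, ph, pw = pc
            full = np.zeros((dprob.shape[0], dprob.shape[1], h + ph, w + pw),
                            dtype=F32)
            full[:, :, :h, :w] = dprob
            dprob = full  # reflect-pad adjoint ignored for the cropped rim
        dz4 = self.head.backward(self.head_sigmoid.backward(dprob))
        d4 = self.config.decoder_widths[3]
        dz4_learned = dz4[:, :d4]
        dz3 = self.dec4_up.backward(self.dec4_refine.backward(
            self.dec4_norm.backward(self.dec4_relu.backward(dz4_learned))))
        dx1 = dz3.copy()
        dz2 = self.dec3_up.backward(
            self.dec3_norm.backward(self.dec3_relu.backward(dz3)))
        dx2 = dz2.copy()
        dz1 = self.dec2_up.backward(self.dec2_norm.backward(
            self.dec2_relu.backward(self.dec2_drop.backward(dz2))))
        dx3_skip = self.skip1_proj.backward(dz1)
        dy = self.dec1_up.backward(self.dec1_refine.backward(
            self.dec1_norm.backward(self.dec1_relu.backward(
                self.dec1_drop.backward(dz1)))))
        dx4 = self.bottleneck1.backward(self.bottleneck2.backward(dy))
        dx3 = self.enc4_down.backward(self.enc4_refine.backward(
            self.enc4_norm.backward(self.enc4_relu.backward(
                self.enc4_drop.backward(dx4)))))
        dx3 += dx3_skip
        dx2 += self.enc3_down.backward(self.enc3_norm.backward(
            self.enc3_relu.backward(self.enc3_drop.backward(dx3))))
        dx1 += self.enc2_down.backward(self.enc2_norm.backward(
            self.enc2_relu.backward(self.enc2_drop.backward(dx2))))
        self.enc1_down.backward(self.enc1_refine.backward(
            self.enc1_relu.backward(dx1)))

    # -- (de)serialization ----------------------------------------------------
    def state_arrays(self) -> list:
        return [p for p, _ in self.params()]

    def save(self, path, extra: dict | None = None) -> None:
        """Single-archive checkpoint: weights + architecture + metadata."""
        arrays = {f"p{i}": p for i, p in enumerate(self.state_arrays())}
        meta = {"net_config": self.config.dump(), "extra": extra or {}}
        np.savez_compressed(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> tuple:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            ncfg = dict(meta["net_config"])
            ncfg.pop("prehead_channels", None)
            ncfg["encoder_widths"] = tuple(ncfg["encoder_widths"])
            ncfg["decoder_widths"] = tuple(ncfg["decoder_widths"])
            net = cls(NetConfig(**ncfg))
            for i, (p, _) in enumerate(net.params()):
                p[...] = data[f"p{i}"]
        return net, meta["extra"]
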