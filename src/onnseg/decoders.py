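"""Decoder architectures over a five-stage encoder.

All decoders return a feature map at the input spatial resolution; the 1x1
two-channel head and SoftMax live in :mod:`onnseg.model_zoo`.  The
``selfonn_unet`` decoder uses the U-Net topology with every convolutional
unit replaced by a tanh-activated Self-ONN layer (bias, no normalization:
tanh already bounds the activations so the power series stays conditioned).
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor, concatenate, upsample_bilinear

__all__ = ["UnetDecoder", "UnetPPDecoder", "FPNDecoder"]


def _conv_unit(in_ch, out_ch, rng, use_batchnorm=True, activation="relu"):
    layers = [nn.Conv2d(in_ch, out_ch, 3, padding=1, bias=not use_batchnorm, rng=rng)]
    if use_batchnorm:
        layers.append(nn.BatchNorm2d(out_ch))
    if activation == "relu":
        layers.append(nn.ReLU())
    elif activation == "tanh":
        layers.append(nn.Tanh())
    elif activation != "none":
        raise ValueError(f"unknown activation {activation!r}")
    return nn.Sequential(*layers)


def _selfonn_unit(in_ch, out_ch, q, rng, activation="tanh"):
    layers = [nn.SelfONN2d(in_ch, out_ch, 3, q=q, padding=1, bias=True, rng=rng)]
    if activation == "tanh":
        layers.append(nn.Tanh())
    elif activation != "none":
        raise ValueError(f"unknown activation {activation!r}")
    return nn.Sequential(*layers)


class _DecoderBlock(nn.Module):
    """Upsample 2x, concatenate the skip, then two conv units."""

    def __init__(self, in_ch, skip_ch, out_ch, unit_factory):
        super().__init__()
        self.skip_ch = skip_ch
        self.unit1 = unit_factory(in_ch + skip_ch, out_ch)
        self.unit2 = unit_factory(out_ch, out_ch)

    def forward(self, x, skip=None):
        h, w = x.shape[2], x.shape[3]
        x = upsample_bilinear(x, (h * 2, w * 2))
        if skip is not None:
            if skip.shape[1] != self.skip_ch:
                raise ValueError(f"skip has {skip.shape[1]} channels, expected {self.skip_ch}")
            x = concatenate([x, skip], axis=1)
        return self.unit2(self.unit1(x))


def _make_unit_factory(kind, q, rng, use_batchnorm=True, activation=None):
    if kind == "selfonn":
        act = "tanh" if activation is None else activation
        return lambda i, o: _selfonn_unit(i, o, q, rng, activation=act)
    act = "relu" if activation is None else activation
    return lambda i, o: _conv_unit(i, o, rng, use_batchnorm=use_batchnorm, activation=act)


class UnetDecoder(nn.Module):
    """Five upsampling blocks with encoder skips; the last block has none.

    ``unit_kind='selfonn'`` gives the Self-ONN U-Net decoder;
    ``selfonn_bottleneck_only=True`` restricts Self-ONN units to the deepest
    block and keeps plain conv units elsewhere.
    """

    def __init__(self, encoder_channels, decoder_channels=(256, 128, 64, 32, 16),
                 unit_kind="conv", q=3, use_batchnorm=True, activation=None,
                 selfonn_bottleneck_only=False, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c1, c2, c3, c4, c5 = encoder_channels
        skips = [c4, c3, c2, c1, 0]
        ins = [c5] + list(decoder_channels[:-1])
        self.blocks = []
        for i in range(5):
            kind = unit_kind
            if unit_kind == "selfonn" and selfonn_bottleneck_only and i > 0:
                kind = "conv"
            factory = _make_unit_factory(kind, q, rng, use_batchnorm, activation)
            self.blocks.append(_DecoderBlock(ins[i], skips[i], decoder_channels[i], factory))
        self.out_channels = decoder_channels[-1]

    def forward(self, features):
        f1, f2, f3, f4, f5 = features
        skips = [f4, f3, f2, f1, None]
        x = f5
        for block, skip in zip(self.blocks, skips):
            x = block(x, skip)
        return x


class UnetPPDecoder(nn.Module):
    """Nested dense skip pathways (U-Net++) over the 5-level feature grid."""

    def __init__(self, encoder_channels, decoder_channels=(256, 128, 64, 32, 16),
                 unit_kind="conv", q=3, use_batchnorm=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        factory = _make_unit_factory(unit_kind, q, rng, use_batchnorm)
        # node channels per pyramid level (level 0 = stride 2 ... level 4 = stride 32)
        level_ch = list(decoder_channels[::-1])  # shallow levels narrow
        self.node_units = {}
        ch = {(i, 0): encoder_channels[i] for i in range(5)}
        for j in range(1, 5):
            for i in range(5 - j):
                in_ch = sum(ch[(i, t)] for t in range(j)) + ch[(i + 1, j - 1)]
                out_ch = level_ch[i]
                self.node_units[(i, j)] = factory(in_ch, out_ch)
                ch[(i, j)] = out_ch
        self.units = list(self.node_units.values())  # parameter registration
        self.final = _DecoderBlock(ch[(0, 4)], 0, decoder_channels[-1], factory)
        self.out_channels = decoder_channels[-1]

    def forward(self, features):
        x = {(i, 0): features[i] for i in range(5)}
        for j in range(1, 5):
            for i in range(5 - j):
                below = x[(i + 1, j - 1)]
                h, w = below.shape[2], below.shape[3]
                up = upsample_bilinear(below, (h * 2, w * 2))
                cat = concatenate([x[(i, t)] for t in range(j)] + [up], axis=1)
                x[(i, j)] = self.node_units[(i, j)](cat)
        return self.final(x[(0, 4)])


class FPNDecoder(nn.Module):
    """Feature pyramid: 1x1 lateral projections, top-down 2x upsampling,
    per-level 3x3 prediction maps upsampled to input size, summed, then a
    final 3x3 convolution."""

    def __init__(self, encoder_channels, pyramid_channels=256,
                 segmentation_channels=128, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c1, c2, c3, c4, c5 = encoder_channels
        self.laterals = [nn.Conv2d(c, pyramid_channels, 1, rng=rng) for c in (c5, c4, c3, c2)]
        self.seg_blocks = [
            nn.Sequential(nn.Conv2d(pyramid_channels, segmentation_channels, 3, padding=1, rng=rng),
                          nn.ReLU())
            for _ in range(4)
        ]
        self.merge_conv = nn.Sequential(
            nn.Conv2d(segmentation_channels, segmentation_channels, 3, padding=1, rng=rng),
            nn.ReLU(),
        )
        self.out_channels = segmentation_channels

    def forward(self, features):
        f1, f2, f3, f4, f5 = features
        target = (f1.shape[2] * 2, f1.shape[3] * 2)  # input spatial size
        pyramid = []
        x = self.laterals[0](f5)
        pyramid.append(x)
        for lateral, feat in zip(self.laterals[1:], (f4, f3, f2)):
            h, w = feat.shape[2], feat.shape[3]
            x = lateral(feat) + upsample_bilinear(x, (h, w))
            pyramid.append(x)
        merged = None
        for seg, p in zip(self.seg_blocks, pyramid):
            m = upsample_bilinear(seg(p), target)
            merged = m if merged is None else merged + m
        return self.merge_conv(merged)
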