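"""Multi-scale feature extractors used as segmentation backbones.

Each encoder maps an image of shape (N, C, H, W), with H and W divisible by
32, to five feature maps at strides 2, 4, 8, 16 and 32.  The ResNet and
DenseNet families follow the standard reference architectures (classifier
heads removed), so their trainable-parameter structure matches the published
models; the tiny family is a deliberately small five-stage network for tests
and desk-scale experiments.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import concatenate

__all__ = ["TinyEncoder", "ResNetEncoder", "DenseNetEncoder", "ENCODER_FAMILIES"]


def _check_divisible(x):
    h, w = x.shape[2], x.shape[3]
    if h % 32 or w % 32:
        raise ValueError(f"input spatial size {h}x{w} must be divisible by 32")


class TinyEncoder(nn.Module):
    """Five stride-2 conv stages; total parameters well under 100k."""

    def __init__(self, in_channels: int = 1, stage_channels=(8, 12, 16, 24, 32),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.out_channels = list(stage_channels)
        chans = [in_channels] + list(stage_channels)
        self.stages = [
            nn.Sequential(
                nn.Conv2d(chans[i], chans[i + 1], 3, stride=2, padding=1, bias=False, rng=rng),
                nn.BatchNorm2d(chans[i + 1]),
                nn.ReLU(),
            )
            for i in range(5)
        ]

    def forward(self, x):
        _check_divisible(x)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats


# ---------------------------------------------------------------------------
# ResNet family
# ---------------------------------------------------------------------------

class _BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, in_ch, out_ch, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch),
            )

    def forward(self, x):
        identity = x if self.downsample is None else self.downsample(x)
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (y + identity).relu()


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch, mid_ch, stride, rng):
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.conv1 = nn.Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid_ch)
        self.conv2 = nn.Conv2d(mid_ch, mid_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid_ch)
        self.conv3 = nn.Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.downsample = None
        if stride != 1 or in_ch != out_ch:
            self.downsample = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(out_ch),
            )

    def forward(self, x):
        identity = x if self.downsample is None else self.downsample(x)
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y)).relu()
        y = self.bn3(self.conv3(y))
        return (y + identity).relu()


_RESNET_CFG = {
    "resnet18": (_BasicBlock, (2, 2, 2, 2)),
    "resnet50": (_Bottleneck, (3, 4, 6, 3)),
    "resnet101": (_Bottleneck, (3, 4, 23, 3)),
    "resnet152": (_Bottleneck, (3, 8, 36, 3)),
}


class ResNetEncoder(nn.Module):
    def __init__(self, family: str = "resnet18", in_channels: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        block, layers = _RESNET_CFG[family]
        self.conv1 = nn.Conv2d(in_channels, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(64)
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        self.layers = []
        in_ch = 64
        out_list = [64]
        for i, (width, n_blocks) in enumerate(zip((64, 128, 256, 512), layers)):
            stride = 1 if i == 0 else 2
            blocks = []
            for j in range(n_blocks):
                blocks.append(block(in_ch, width, stride if j == 0 else 1, rng))
                in_ch = width * block.expansion
            self.layers.append(nn.Sequential(*blocks))
            out_list.append(in_ch)
        self.out_channels = out_list

    def forward(self, x):
        _check_divisible(x)
        f1 = self.bn1(self.conv1(x)).relu()
        x = self.maxpool(f1)
        feats = [f1]
        for layer in self.layers:
            x = layer(x)
            feats.append(x)
        return feats


# ---------------------------------------------------------------------------
# DenseNet family
# ---------------------------------------------------------------------------

class _DenseLayer(nn.Module):
    def __init__(self, in_ch, growth, bn_size, rng):
        super().__init__()
        mid = bn_size * growth
        self.norm1 = nn.BatchNorm2d(in_ch)
        self.conv1 = nn.Conv2d(in_ch, mid, 1, bias=False, rng=rng)
        self.norm2 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, growth, 3, padding=1, bias=False, rng=rng)

    def forward(self, x):
        y = self.conv1(self.norm1(x).relu())
        y = self.conv2(self.norm2(y).relu())
        return concatenate([x, y], axis=1)


class _Transition(nn.Module):
    def __init__(self, in_ch, rng):
        super().__init__()
        self.norm = nn.BatchNorm2d(in_ch)
        self.conv = nn.Conv2d(in_ch, in_ch // 2, 1, bias=False, rng=rng)
        self.pool = nn.AvgPool2d(2, 2)

    def forward(self, x):
        return self.pool(self.conv(self.norm(x).relu()))


_DENSENET_CFG = {
    # family: (growth rate, init features, block layer counts)
    "densenet121": (32, 64, (6, 12, 24, 16)),
    "densenet161": (48, 96, (6, 12, 36, 24)),
    "densenet201": (32, 64, (6, 12, 48, 32)),
}


class DenseNetEncoder(nn.Module):
    def __init__(self, family: str = "densenet201", in_channels: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        growth, init_feat, block_cfg = _DENSENET_CFG[family]
        bn_size = 4
        self.conv0 = nn.Conv2d(in_channels, init_feat, 7, stride=2, padding=3, bias=False, rng=rng)
        self.norm0 = nn.BatchNorm2d(init_feat)
        self.pool0 = nn.MaxPool2d(3, 2, 1)
        self.blocks = []
        self.transitions = []
        ch = init_feat
        out_list = [init_feat]
        for bi, n_layers in enumerate(block_cfg):
            layers = []
            for _ in range(n_layers):
                layers.append(_DenseLayer(ch, growth, bn_size, rng))
                ch += growth
            self.blocks.append(nn.Sequential(*layers))
            out_list.append(ch)
            if bi != len(block_cfg) - 1:
                self.transitions.append(_Transition(ch, rng))
                ch //= 2
        self.norm5 = nn.BatchNorm2d(out_list[-1])
        self.out_channels = out_list

    def forward(self, x):
        _check_divisible(x)
        f1 = self.norm0(self.conv0(x)).relu()
        x = self.pool0(f1)
        feats = [f1]
        for i, block in enumerate(self.blocks):
            x = block(x)
            feats.append(x)
            if i < len(self.transitions):
                x = self.transitions[i](x)
        feats[-1] = self.norm5(feats[-1]).relu()
        return feats


ENCODER_FAMILIES = {
    "tiny": TinyEncoder,
    **{name: ResNetEncoder for name in _RESNET_CFG},
    **{name: DenseNetEncoder for name in _DENSENET_CFG},
}
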