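"""Residual-network backbones producing fixed-length tooth representations.

Both variants take a single-channel (grayscale) image batch in [0,1] and end
in global average pooling, so the output is a (B, d) representation matrix
with the classifier layer left off.

* ``TinyBackbone`` — a desk-scale network with the same residual-block
  structure as ResNet-18 but 3 blocks and d = 64 by default (input side 48);
  used throughout the tests and the synthetic experiments.
* ``ResNet18Backbone`` — the full 18-trainable-layer architecture
  (7x7 stem, four 2-block stages, widths 64..512, d = 512), with a
  single-channel first convolution instead of the stock RGB one.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    MaxPool2d,
    Module,
    ReLU,
    ResidualBlock,
    Sequential,
)

__all__ = ["TinyBackbone", "ResNet18Backbone", "make_backbone"]


class TinyBackbone(Sequential):
    def __init__(self, d: int = 64, rng=None, dtype=np.float32) -> None:
        if d % 4 != 0 or d < 8:
            raise ValueError("tiny backbone width d must be a multiple of 4 and >= 8")
        w = d // 4
        super().__init__(
            Conv2d(1, w, 3, stride=2, pad=1, rng=rng, dtype=dtype),
            BatchNorm2d(w, dtype=dtype),
            ReLU(),
            ResidualBlock(w, 2 * w, stride=2, rng=rng, dtype=dtype),
            ResidualBlock(2 * w, 4 * w, stride=2, rng=rng, dtype=dtype),
            ResidualBlock(4 * w, 4 * w, stride=1, rng=rng, dtype=dtype),
            GlobalAvgPool(),
        )
        self.out_dim = d
        self.default_side = 48


class ResNet18Backbone(Sequential):
    def __init__(self, rng=None, dtype=np.float32) -> None:
        stages: list[Module] = [
            Conv2d(1, 64, 7, stride=2, pad=3, rng=rng, dtype=dtype),
            BatchNorm2d(64, dtype=dtype),
            ReLU(),
            MaxPool2d(3, 2, 1),
        ]
        widths = [64, 128, 256, 512]
        in_ch = 64
        for i, ch in enumerate(widths):
            stride = 1 if i == 0 else 2
            stages.append(ResidualBlock(in_ch, ch, stride=stride, rng=rng, dtype=dtype))
            stages.append(ResidualBlock(ch, ch, stride=1, rng=rng, dtype=dtype))
            in_ch = ch
        stages.append(GlobalAvgPool())
        super().__init__(*stages)
        self.out_dim = 512
        self.default_side = 112


def make_backbone(name: str, d: int | None = None, rng=None, dtype=np.float32) -> Sequential:
    if name == "tiny":
        return TinyBackbone(d=d or 64, rng=rng, dtype=dtype)
    if name == "resnet18":
        if d not in (None, 512):
            raise ValueError("resnet18 backbone has fixed d = 512")
        return ResNet18Backbone(rng=rng, dtype=dtype)
    raise ValueError(f"unknown backbone {name!r}")
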