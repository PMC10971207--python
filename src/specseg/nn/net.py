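"""Fully convolutional segmentation networks built from the NumPy layers.

Two backbones are provided behind one interface:

* ``resnet50`` — the standard 50-layer residual network (bottleneck blocks,
  stage widths 256/512/1024/2048, output stride 32) with an FCN head, the
  architecture used for the real-tissue experiments;
* ``reduced`` — a width- and depth-scaled residual FCN (output stride 4)
  sized for CPU desk-scale experiments on phantom sections.

Networks map (B, C, H, W) inputs to per-pixel class scores (B, n_classes,
H, W) for any H, W divisible by the backbone's stride product.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2d, Layer, MaxPool2d, NearestUpsample, Param, ReLU

__all__ = ["SegmentationNet", "build_network", "BACKBONES"]


class _Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, gy):
        for l in reversed(self.layers):
            gy = l.backward(gy)
        return gy

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def train(self, mode=True):
        for l in self.layers:
            l.train(mode)

    def children(self):
        out = []
        for l in self.layers:
            out.extend(l.children() if hasattr(l, "children") else [l])
        return out


class _Residual(Layer):
    """Residual unit: y = relu(F(x) + proj(x)); F given as a layer list."""

    def __init__(self, body: _Sequential, proj: _Sequential | None = None):
        self.body = body
        self.proj = proj
        self.relu = ReLU()

    def forward(self, x):
        y = self.body.forward(x)
        skip = self.proj.forward(x) if self.proj is not None else x
        return self.relu.forward(y + skip)

    def backward(self, gy):
        g = self.relu.backward(gy)
        gx_body = self.body.backward(g)
        gx_skip = self.proj.backward(g) if self.proj is not None else g
        return gx_body + gx_skip

    def parameters(self):
        ps = self.body.parameters()
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps

    def train(self, mode=True):
        self.body.train(mode)
        if self.proj is not None:
            self.proj.train(mode)

    def children(self):
        out = self.body.children()
        if self.proj is not None:
            out.extend(self.proj.children())
        out.append(self.relu)
        return out


class SegmentationNet(Layer):
    def __init__(self, trunk: _Sequential, stride_product: int, in_channels: int, n_classes: int, backbone: str):
        self.trunk = trunk
        self.stride_product = stride_product
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.backbone = backbone

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (B, {self.in_channels}, H, W) input, got {x.shape}"
            )
        if x.shape[2] % self.stride_product or x.shape[3] % self.stride_product:
            raise ValueError(
                f"H, W must be divisible by stride product {self.stride_product}"
            )
        return self.trunk.forward(np.ascontiguousarray(x, dtype=np.float32))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.trunk.backward(gy)

    def parameters(self) -> list[Param]:
        return self.trunk.parameters()

    def train(self, mode: bool = True):
        self.trunk.train(mode)

    # --- checkpointing ---------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.trunk.children()):
            for k, v in layer.state().items():
                out[f"{i}.{k}"] = v
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.trunk.children()):
            keys = layer.state().keys()
            if keys:
                layer.load_state({k: arrays[f"{i}.{k}"] for k in keys})

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


def _cbr(in_ch, out_ch, k, stride, rng) -> list[Layer]:
    return [Conv2d(in_ch, out_ch, k, stride=stride, bias=False, rng=rng), BatchNorm2d(out_ch), ReLU()]


def _basic_block(ch, rng) -> _Residual:
    body = _Sequential(
        Conv2d(ch, ch, 3, bias=False, rng=rng), BatchNorm2d(ch), ReLU(),
        Conv2d(ch, ch, 3, bias=False, rng=rng), BatchNorm2d(ch),
    )
    return _Residual(body)


def _bottleneck(in_ch, mid_ch, stride, rng) -> _Residual:
    out_ch = mid_ch * 4
    body = _Sequential(
        Conv2d(in_ch, mid_ch, 1, bias=False, rng=rng), BatchNorm2d(mid_ch), ReLU(),
        Conv2d(mid_ch, mid_ch, 3, stride=stride, bias=False, rng=rng), BatchNorm2d(mid_ch), ReLU(),
        Conv2d(mid_ch, out_ch, 1, bias=False, rng=rng), BatchNorm2d(out_ch),
    )
    proj = None
    if stride != 1 or in_ch != out_ch:
        proj = _Sequential(
            Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng), BatchNorm2d(out_ch)
        )
    return _Residual(body, proj)


class _InputSkipRefine(Layer):
    """Coarse logits from the body, refined by a full-resolution conv that
    sees the input image alongside the upsampled logits (residual form).

    The body works at a coarse stride for speed; the refinement conv restores
    boundary detail from the raw channels, which carry the class contrast.
    """

    def __init__(self, body: _Sequential, refine: Conv2d, in_channels: int):
        self.body = body
        self.refine = refine
        self.in_channels = in_channels

    def forward(self, x):
        coarse = self.body.forward(x)
        z = np.concatenate([x, coarse], axis=1)
        return coarse + self.refine.forward(z)

    def backward(self, gy):
        gz = self.refine.backward(gy)
        g_coarse = gz[:, self.in_channels:] + gy
        return self.body.backward(g_coarse) + gz[:, : self.in_channels]

    def parameters(self):
        return self.body.parameters() + self.refine.parameters()

    def train(self, mode=True):
        self.body.train(mode)
        self.refine.train(mode)

    def children(self):
        return self.body.children() + [self.refine]


def _build_reduced(in_channels: int, n_classes: int, rng, width: int = 12) -> SegmentationNet:
    w = width
    layers: list[Layer] = []
    layers += _cbr(in_channels, w, 3, 2, rng)
    layers += _cbr(w, 2 * w, 3, 2, rng)
    layers += _cbr(2 * w, 2 * w, 3, 2, rng)
    layers += [_basic_block(2 * w, rng), _basic_block(2 * w, rng)]
    layers += [Conv2d(2 * w, n_classes, 1, rng=rng), NearestUpsample(8)]
    body = _Sequential(*layers)
    refine = Conv2d(in_channels + n_classes, n_classes, 3, rng=rng)
    trunk = _Sequential(_InputSkipRefine(body, refine, in_channels))
    return SegmentationNet(trunk, 8, in_channels, n_classes, "reduced")


def _build_resnet50_fcn(in_channels: int, n_classes: int, rng) -> SegmentationNet:
    layers: list[Layer] = []
    layers += [Conv2d(in_channels, 64, 7, stride=2, pad=3, bias=False, rng=rng),
               BatchNorm2d(64), ReLU(), MaxPool2d(3, 2, 1)]
    in_ch = 64
    for mid, n_blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
        for b in range(n_blocks):
            layers.append(_bottleneck(in_ch, mid, stride if b == 0 else 1, rng))
            in_ch = mid * 4
    # FCN head: 3x3 conv, BN, ReLU, 1x1 classifier, upsample to input grid
    layers += _cbr(2048, 512, 3, 1, rng)
    layers += [Conv2d(512, n_classes, 1, rng=rng), NearestUpsample(32)]
    return SegmentationNet(_Sequential(*layers), 32, in_channels, n_classes, "resnet50")


BACKBONES = {"reduced": _build_reduced, "resnet50": _build_resnet50_fcn}


def build_network(
    in_channels: int,
    n_classes: int,
    backbone: str = "resnet50",
    rng: np.random.Generator | None = None,
) -> SegmentationNet:
    if backbone not in BACKBONES:
        raise ValueError(f"unknown backbone {backbone!r}; choose from {sorted(BACKBONES)}")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = rng or np.random.default_rng(0)
    return BACKBONES[backbone](in_channels, n_classes, rng)
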