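"""The truncated depthwise-separable classification network.

The classifier is a compact variant of the MobileNet family: an initial
3×3 standard convolution (32 filters, stride 2) followed by a prefix of
the thirteen depthwise-separable blocks — each block a depthwise 3×3
convolution and a pointwise 1×1 convolution, with batch normalization and
ReLU after every convolution — and a classification head of global average
pooling, dropout, a 2-unit dense layer and softmax. With the default
truncation after block 7 the network has 1 + 7×2 = 15 convolution layers
and stops at 512 channels, skipping the parameter-heavy 512→1024 blocks of
the full 27-convolution stack.

The module separates the *description* of the network
(:class:`NetworkSpec`, with closed-form parameter counting) from its
*realization* as a trainable graph (:func:`build_network`), so the
structure can be audited independently of any numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import nn

CONV_KINDS = ("standard_conv", "depthwise_conv", "pointwise_conv")

#: The thirteen depthwise-separable blocks of the full architecture as
#: (depthwise stride, pointwise output filters) at width multiplier 1.
FULL_BLOCKS = (
    (1, 64),
    (2, 128),
    (1, 128),
    (2, 256),
    (1, 256),
    (2, 512),
    (1, 512),
    (1, 512),
    (1, 512),
    (1, 512),
    (1, 512),
    (2, 1024),
    (1, 1024),
)


class ParameterError(ValueError):
    """Raised for out-of-range architecture configuration."""


class ConstructionError(ValueError):
    """Raised when a spec cannot be realized as a trainable graph."""


@dataclass(frozen=True)
class LayerSpec:
    """Description of a single layer.

    ``filters`` is the output channel/unit count for conv and dense
    layers; ``input_channels`` the incoming channel count; ``rate`` the
    dropout rate for dropout layers.
    """

    kind: str
    filters: Optional[int] = None
    kernel: Optional[tuple[int, int]] = None
    stride: Optional[int] = None
    input_channels: Optional[int] = None
    rate: Optional[float] = None

    def __post_init__(self):
        if self.kind in CONV_KINDS:
            if not (self.filters and self.filters > 0):
                raise ParameterError(f"{self.kind} needs positive filters")
            if not (self.stride and self.stride > 0):
                raise ParameterError(f"{self.kind} needs positive stride")
            if self.kernel is None or min(self.kernel) < 1:
                raise ParameterError(f"{self.kind} needs a positive kernel")


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer list plus input size; supports structural audits."""

    layers: tuple[LayerSpec, ...]
    input_size: tuple[int, int, int] = (224, 224, 3)

    @property
    def conv_layer_count(self) -> int:
        return sum(1 for l in self.layers if l.kind in CONV_KINDS)

    @property
    def head_kinds(self) -> tuple[str, ...]:
        return tuple(l.kind for l in self.layers[-4:])


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    truncate_after_block : how many depthwise-separable blocks to keep
        (1–13); 7 gives the default 15-convolution network.
    width_multiplier : scales every channel count (1.0 = full width).
    """

    input_size: tuple[int, int, int] = (224, 224, 3)
    dropout_rate: float = 0.25
    n_classes: int = 2
    truncate_after_block: int = 7
    width_multiplier: float = 1.0

    def __post_init__(self):
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ParameterError("n_classes must be at least 2")
        if not 1 <= self.truncate_after_block <= len(FULL_BLOCKS):
            raise ParameterError(
                f"truncate_after_block must lie in [1, {len(FULL_BLOCKS)}]"
            )
        if self.width_multiplier <= 0:
            raise ParameterError("width_multiplier must be positive")


def _width(filters: int, multiplier: float) -> int:
    return max(1, int(round(filters * multiplier)))


def enhanced_mobilenet_spec(cfg: ModelConfig = ModelConfig()) -> NetworkSpec:
    """Build the truncated network description.

    Layer order: standard conv (+BN+ReLU), ``truncate_after_block``
    depthwise-separable blocks (each depthwise 3×3 and pointwise 1×1, BN
    and ReLU after each conv), then [global_avg_pool, dropout, dense,
    softmax]. The default configuration yields 15 convolution layers.
    """
    wm = cfg.width_multiplier
    layers: list[LayerSpec] = []
    in_ch = cfg.input_size[2]

    first = _width(32, wm)
    layers.append(LayerSpec("standard_conv", filters=first, kernel=(3, 3),
                            stride=2, input_channels=in_ch))
    layers.append(LayerSpec("batch_norm", input_channels=first))
    layers.append(LayerSpec("relu"))
    channels = first

    for stride, filters in FULL_BLOCKS[: cfg.truncate_after_block]:
        out_ch = _width(filters, wm)
        layers.append(LayerSpec("depthwise_conv", filters=channels, kernel=(3, 3),
                                stride=stride, input_channels=channels))
        layers.append(LayerSpec("batch_norm", input_channels=channels))
        layers.append(LayerSpec("relu"))
        layers.append(LayerSpec("pointwise_conv", filters=out_ch, kernel=(1, 1),
                                stride=1, input_channels=channels))
        layers.append(LayerSpec("batch_norm", input_channels=out_ch))
        layers.append(LayerSpec("relu"))
        channels = out_ch

    layers.append(LayerSpec("global_avg_pool", input_channels=channels))
    layers.append(LayerSpec("dropout", rate=cfg.dropout_rate))
    layers.append(LayerSpec("dense", filters=cfg.n_classes, input_channels=channels))
    layers.append(LayerSpec("softmax"))
    return NetworkSpec(layers=tuple(layers), input_size=cfg.input_size)


def count_parameters(spec: NetworkSpec) -> int:
    """Closed-form trainable-parameter count of a spec.

    Depthwise k×k over C channels: k²·C. Pointwise C→F: C·F. Standard
    k×k C→F: k²·C·F. Batch norm over C channels: 2·C (scale and shift).
    Dense C→F: C·F + F. Convolutions carry no bias.
    """
    total = 0
    for l in spec.layers:
        if l.kind == "standard_conv":
            total += l.kernel[0] * l.kernel[1] * l.input_channels * l.filters
        elif l.kind == "depthwise_conv":
            total += l.kernel[0] * l.kernel[1] * l.input_channels
        elif l.kind == "pointwise_conv":
            total += l.input_channels * l.filters
        elif l.kind == "batch_norm":
            total += 2 * l.input_channels
        elif l.kind == "dense":
            total += l.input_channels * l.filters + l.filters
    return total


def build_network(spec: NetworkSpec, seed: int) -> nn.Network:
    """Realize a spec as a trainable network with seeded initialization."""
    head = spec.head_kinds
    if head != ("global_avg_pool", "dropout", "dense", "softmax"):
        raise ConstructionError(
            f"head must be [global_avg_pool, dropout, dense, softmax], got {head}"
        )
    ss = np.random.SeedSequence(seed)
    init_rng = np.random.default_rng(ss.spawn(1)[0])
    drop_rng = np.random.default_rng(ss.spawn(1)[0])

    layers: list[nn.Layer] = []
    for idx, l in enumerate(spec.layers):
        name = f"{l.kind}_{idx}"
        if l.kind == "standard_conv":
            layers.append(nn.Conv2D(l.input_channels, l.filters, l.stride,
                                    init_rng, kernel=l.kernel[0], name=name))
        elif l.kind == "depthwise_conv":
            layers.append(nn.DepthwiseConv2D(l.input_channels, l.stride,
                                             init_rng, name=name))
        elif l.kind == "pointwise_conv":
            layers.append(nn.PointwiseConv2D(l.input_channels, l.filters,
                                             init_rng, name=name))
        elif l.kind == "batch_norm":
            layers.append(nn.BatchNorm(l.input_channels, name=name))
        elif l.kind == "relu":
            layers.append(nn.ReLU())
        elif l.kind == "global_avg_pool":
            layers.append(nn.GlobalAvgPool())
        elif l.kind == "dropout":
            layers.append(nn.Dropout(l.rate, drop_rng))
        elif l.kind == "dense":
            layers.append(nn.Dense(l.input_channels, l.filters, init_rng, name=name))
        elif l.kind == "softmax":
            layers.append(nn.Softmax())
        else:
            raise ConstructionError(f"unknown layer kind {l.kind!r}")
    network = nn.Network(layers)
    expected = count_parameters(spec)
    if network.parameter_count != expected:
        raise ConstructionError(
            f"realized network has {network.parameter_count} parameters, "
            f"spec counts {expected}"
        )
    return network


def summarize_spec(spec: NetworkSpec) -> str:
    """Human-readable layer table with shapes and parameter counts."""
    lines = [f"{'layer':<18}{'filters':>8}{'stride':>7}{'in_ch':>7}{'params':>10}"]
    for l in spec.layers:
        sub = NetworkSpec(layers=(l,), input_size=spec.input_size)
        lines.append(
            f"{l.kind:<18}{l.filters or '':>8}{l.stride or '':>7}"
            f"{l.input_channels or '':>7}{count_parameters(sub):>10}"
        )
    lines.append(f"{'total':<18}{'':>8}{'':>7}{'':>7}{count_parameters(spec):>10}")
    lines.append(f"conv layers: {spec.conv_layer_count}")
    return "\n".join(lines)
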