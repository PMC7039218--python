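"""Compact CNN for 8-channel scalogram inputs.

The network body is four 3x3 convolutions.  A layer whose output width
(channel count) is larger than its input width uses stride 2 (spatial
halving); all other layers use stride 1.  Padding is 1 everywhere.  The
classifier head is adaptive mean pooling to 1x1 followed by a 1x1
convolution to the class logits — there is no fully connected layer.

The default configuration (widths 16, 32, 39, 48, channel-wise parametric
rectifiers, no convolution or head biases) was frozen by the constrained
integer search in ``scripts/width_search.py`` so that the 7-class model has
exactly 34311 learnable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "EMGNetConfig",
    "DEFAULT_CONV_WIDTHS",
    "build_emgnet",
    "count_parameters",
    "forward",
    "cross_entropy",
    "architecture_summary",
    "save_checkpoint",
    "load_checkpoint",
]

#: Frozen by scripts/width_search.py: with channel-wise PReLU slopes and no
#: biases these widths give exactly 34311 parameters at n_classes=7.
DEFAULT_CONV_WIDTHS: tuple[int, int, int, int] = (16, 32, 39, 48)


@dataclass(frozen=True)
class EMGNetConfig:
    """Architecture hyper-parameters.

    ``conv_widths`` are the output channel counts of the four body layers.
    Stride is 2 exactly on layers whose width increases over their input,
    else 1 with padding 1.
    """

    in_channels: int = 8
    input_size: tuple[int, int] = (15, 25)
    conv_widths: tuple[int, int, int, int] = DEFAULT_CONV_WIDTHS
    activation: str = "prelu"  # "prelu" | "relu"
    prelu_shared: bool = False
    use_bias: bool = False
    head_bias: bool = False
    pool: str = "mean"  # "mean" | "max"
    n_classes: int = 7

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.n_classes < 1:
            raise ValueError("in_channels and n_classes must be >= 1")
        if len(self.conv_widths) != 4:
            raise ValueError("exactly 4 convolutional body layers are required")
        if any(w < 1 for w in self.conv_widths):
            raise ValueError("conv widths must be positive")
        if self.activation not in ("prelu", "relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.pool not in ("mean", "max"):
            raise ValueError(f"unknown pool {self.pool!r}")

    def strides(self) -> tuple[int, ...]:
        """Stride per body layer: 2 where the width increases, else 1."""
        prev = self.in_channels
        out = []
        for w in self.conv_widths:
            out.append(2 if w > prev else 1)
            prev = w
        return tuple(out)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EMGNet:
    """Built model: a layer graph plus the config that produced it."""

    config: EMGNetConfig
    graph: nn.Sequential
    layer_shapes: list[tuple] = field(default_factory=list)

    def __call__(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        return forward(self, batch, train=train)


def build_emgnet(config: EMGNetConfig, seed: int = 0) -> EMGNet:
    """Build the network graph with seeded He-style initialization."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    shapes: list[tuple] = []
    h, w = config.input_size
    prev = config.in_channels
    for width, stride in zip(config.conv_widths, config.strides()):
        conv = nn.Conv2d(
            prev, width, kernel_size=3, stride=stride, padding=1,
            bias=config.use_bias, rng=rng,
        )
        h, w = conv.output_shape(h, w)
        if h < 1 or w < 1:
            raise ValueError(
                f"conv widths {config.conv_widths} collapse the "
                f"{config.input_size} input to an empty feature map"
            )
        layers.append(conv)
        if config.activation == "prelu":
            layers.append(nn.PReLU(width, shared=config.prelu_shared))
        else:
            layers.append(nn.ReLU())
        shapes.append((width, h, w))
        prev = width
    layers.append(nn.GlobalAvgPool() if config.pool == "mean" else nn.GlobalMaxPool())
    shapes.append((prev, 1, 1))
    layers.append(
        nn.Conv2d(prev, config.n_classes, kernel_size=1, stride=1, padding=0,
                  bias=config.head_bias, rng=rng)
    )
    layers.append(nn.Flatten())
    shapes.append((config.n_classes,))
    return EMGNet(config=config, graph=nn.Sequential(layers), layer_shapes=shapes)


def count_parameters(model: EMGNet | nn.Sequential) -> int:
    """Total learnable scalars: weights, biases and rectifier slopes."""
    graph = model.graph if isinstance(model, EMGNet) else model
    return graph.n_parameters()


def forward(model: EMGNet, batch: np.ndarray, train: bool = False) -> np.ndarray:
    """Run a batch through the network, returning (B, n_classes) logits."""
    batch = np.asarray(batch, dtype=float)
    cfg = model.config
    expected = (cfg.in_channels,) + tuple(cfg.input_size)
    if batch.ndim == 3:
        batch = batch[None]
    if batch.ndim != 4 or batch.shape[1:] != expected:
        raise ValueError(
            f"expected batch of shape (B, {expected[0]}, {expected[1]}, "
            f"{expected[2]}), got {batch.shape}"
        )
    return model.graph.forward(batch, train=train)


def cross_entropy(predicted_probs, onehot_target, eps: float = 1e-12) -> float:
    """One-hot cross-entropy ``-sum_i y_i * log(y'_i)``.

    ``predicted_probs`` must lie on the probability simplex (within 1e-6);
    probabilities are clamped at ``eps`` for log safety, so the loss of the
    true class having probability 0 is finite but very large.
    """
    p = np.asarray(predicted_probs, dtype=float)
    y = np.asarray(onehot_target, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {y.shape}")
    if np.any(p < -1e-6) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("predicted_probs is not on the probability simplex")
    if not (np.all((y == 0) | (y == 1)) and y.sum() == 1):
        raise ValueError("target must be one-hot")
    return float(-(y * np.log(np.clip(p, eps, None))).sum())


def architecture_summary(model: EMGNet) -> dict:
    """Plain-data summary of layers, shapes and parameter counts."""
    layers = []
    for layer in model.graph.layers:
        layers.append(
            {
                "type": type(layer).__name__,
                "n_parameters": layer.n_parameters(),
                "params": {k: list(v.shape) for k, v in layer.params.items()},
            }
        )
    return {
        "config": model.config.to_dict(),
        "layers": layers,
        "total_parameters": count_parameters(model),
    }


def save_checkpoint(model: EMGNet, path) -> None:
    """Persist weights plus a config fingerprint in a portable .npz."""
    import json

    state = model.graph.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict(), sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> EMGNet:
    import json

    with np.load(path) as data:
        cfg_raw = json.loads(bytes(data["__config__"].tobytes()).decode())
        cfg_raw["input_size"] = tuple(cfg_raw["input_size"])
        cfg_raw["conv_widths"] = tuple(cfg_raw["conv_widths"])
        config = EMGNetConfig(**cfg_raw)
        model = build_emgnet(config, seed=0)
        model.graph.load_state_dict(
            {k: data[k] for k in data.files if k != "__config__"}
        )
    return model
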