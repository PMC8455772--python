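"""The shared convolutional backbone and its two task heads.

One block = 3x3 convolution -> batch normalization -> LeakyReLU.  The
network is organised in resolution levels; every level after the first is
entered through a stride-2 block (which counts toward the block total and
carries the channel increase).  The default topology has 8 levels with
blocks [5, 4, 4, 4, 4, 3, 3, 3] (30 blocks, 7 subsamplings) and channels
[48, 56, 64, 76, 88, 100, 114, 128].

Heads: coordinate regression (linear logits against targets normalized to
[0, 1], MSE loss) or 2-way classification (softmax cross entropy).  The
head reads the final feature map through global average pooling by default;
``head_pool="flatten"`` keeps spatial layout, which small-budget regression
runs need.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from . import nn


class Stage(str, Enum):
    STAGE1 = "STAGE1"  # coarse carina regression on the full model input
    STAGE2 = "STAGE2"  # ETT presence classification on the crop
    STAGE3 = "STAGE3"  # refined carina + tip regression on the crop


class ConfigError(ValueError):
    pass


DEFAULT_BLOCKS: tuple[int, ...] = (5, 4, 4, 4, 4, 3, 3, 3)
DEFAULT_CHANNELS: tuple[int, ...] = (48, 56, 64, 76, 88, 100, 114, 128)

TEST_SCALE_BLOCKS: tuple[int, ...] = (3, 3, 2, 2)
TEST_SCALE_CHANNELS: tuple[int, ...] = (8, 16, 24, 32)
# crop-stage inputs are 8x smaller, so the reduced config affords more width
TEST_SCALE_CROP_CHANNELS: tuple[int, ...] = (12, 24, 36, 48)


@dataclass(frozen=True)
class HeadSpec:
    kind: str  # "regression" | "classification"
    dim: int

    def __post_init__(self) -> None:
        if self.kind not in ("regression", "classification"):
            raise ConfigError(f"unknown head kind {self.kind!r}")
        if self.dim < 1:
            raise ConfigError("head dim must be >= 1")


@dataclass(frozen=True)
class BackboneConfig:
    """Declarative network topology.

    ``levels`` is an ordered tuple of ``(n_blocks, channels)`` pairs, the
    first at full resolution; each later level is entered via one stride-2
    block included in its count.
    """

    levels: tuple[tuple[int, int], ...]
    head: HeadSpec
    input_h: int
    input_w: int
    leaky_slope: float = 0.3
    head_pool: str = "gap"  # "gap" | "flatten"
    bn_momentum: float = 0.1
    head_bias: float = 0.0    # regression heads may start at the frame centre
    head_init_scale: float = 1.0  # scales the head's Xavier init (0 = zero start)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ConfigError("at least one level required")
        chans = [c for _, c in self.levels]
        if any(n < 1 for n, _ in self.levels) or any(c < 1 for c in chans):
            raise ConfigError("block and channel counts must be positive")
        if any(b < a for a, b in zip(chans, chans[1:])):
            raise ConfigError("channel counts must be non-decreasing")
        if self.head_pool not in ("gap", "flatten"):
            raise ConfigError(f"unknown head_pool {self.head_pool!r}")
        min_side = 2 ** self.n_subsamplings
        if min(self.input_h, self.input_w) < min_side:
            raise ConfigError(
                f"input {self.input_h}x{self.input_w} too small for "
                f"{self.n_subsamplings} subsamplings (needs >= {min_side} px per axis)"
            )

    @property
    def n_subsamplings(self) -> int:
        return len(self.levels) - 1

    @property
    def total_blocks(self) -> int:
        return sum(n for n, _ in self.levels)

    def feature_shape(self) -> tuple[int, int]:
        h, w = self.input_h, self.input_w
        for _ in range(self.n_subsamplings):
            h, w = math.ceil(h / 2), math.ceil(w / 2)
        return h, w

    def to_json(self) -> str:
        return json.dumps(
            {
                "levels": [list(lv) for lv in self.levels],
                "head": {"kind": self.head.kind, "dim": self.head.dim},
                "input_h": self.input_h,
                "input_w": self.input_w,
                "leaky_slope": self.leaky_slope,
                "head_pool": self.head_pool,
                "bn_momentum": self.bn_momentum,
                "head_bias": self.head_bias,
                "head_init_scale": self.head_init_scale,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "BackboneConfig":
        d = json.loads(text)
        return cls(
            levels=tuple(tuple(lv) for lv in d["levels"]),
            head=HeadSpec(**d["head"]),
            input_h=d["input_h"],
            input_w=d["input_w"],
            leaky_slope=d["leaky_slope"],
            head_pool=d["head_pool"],
            bn_momentum=d.get("bn_momentum", 0.1),
            head_bias=d.get("head_bias", 0.0),
            head_init_scale=d.get("head_init_scale", 1.0),
        )


def default_config(stage: Stage) -> BackboneConfig:
    """The full-scale published topology for each cascade stage."""
    stage = Stage(stage)
    levels = tuple(zip(DEFAULT_BLOCKS, DEFAULT_CHANNELS))
    if stage is Stage.STAGE1:
        return BackboneConfig(levels, HeadSpec("regression", 2), 512, 512)
    if stage is Stage.STAGE2:
        return BackboneConfig(levels, HeadSpec("classification", 2), 256, 128)
    return BackboneConfig(levels, HeadSpec("regression", 4), 256, 128)


def test_scale_config(stage: Stage) -> BackboneConfig:
    """Reduced topology that trains on one CPU: 4 levels, 10 blocks, 128 px input.

    Structural invariants (stride-2 entries, non-decreasing channels, block
    accounting) match the full-scale config; regression heads use a flatten
    readout, which the short training schedule needs for coordinate output.
    """
    stage = Stage(stage)
    if stage is Stage.STAGE1:
        levels = tuple(zip(TEST_SCALE_BLOCKS, TEST_SCALE_CHANNELS))
        return BackboneConfig(levels, HeadSpec("regression", 2), 128, 128,
                              head_pool="flatten", bn_momentum=0.3,
                              head_bias=0.5, head_init_scale=0.0)
    levels = tuple(zip(TEST_SCALE_BLOCKS, TEST_SCALE_CROP_CHANNELS))
    if stage is Stage.STAGE2:
        return BackboneConfig(levels, HeadSpec("classification", 2), 64, 32,
                              bn_momentum=0.3)
    return BackboneConfig(levels, HeadSpec("regression", 4), 64, 32,
                          head_pool="flatten", bn_momentum=0.3,
                          head_bias=0.5, head_init_scale=0.0)


class Backbone:
    """An instantiated network; use :func:`build` to construct one."""

    def __init__(self, config: BackboneConfig, seed: int = 0, dtype=np.float32) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        self.block_strides: list[int] = []
        self.block_channels: list[int] = []
        c_prev = 1
        for li, (n_blocks, c) in enumerate(config.levels):
            for bi in range(n_blocks):
                stride = 2 if (li > 0 and bi == 0) else 1
                layers.append(nn.Conv2d(c_prev, c, stride=stride, rng=rng, dtype=dtype))
                layers.append(nn.BatchNorm2d(c, momentum=config.bn_momentum, dtype=dtype))
                layers.append(nn.LeakyReLU(config.leaky_slope))
                self.block_strides.append(stride)
                self.block_channels.append(c)
                c_prev = c
        fh, fw = config.feature_shape()
        if config.head_pool == "gap":
            layers.append(nn.GlobalAvgPool())
            d_in = c_prev
        else:
            layers.append(nn.Flatten())
            d_in = c_prev * fh * fw
        head = nn.Linear(d_in, config.head.dim, rng=rng, dtype=dtype)
        if config.head_init_scale != 1.0:
            head.w.value *= config.head_init_scale
        if config.head_bias:
            head.b.value[...] = config.head_bias
        layers.append(head)
        self.net = nn.Sequential(layers)

    # introspection -------------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.block_strides)

    @property
    def n_stride2_blocks(self) -> int:
        return sum(1 for s in self.block_strides if s == 2)

    def blocks_in_level(self, level: int) -> int:
        """Block count of the given resolution level (0-based; levels after
        the first include their stride-2 entry block)."""
        bounds = [i for i, s in enumerate(self.block_strides) if s == 2]
        bounds = [0] + bounds + [len(self.block_strides)]
        if not (0 <= level < len(bounds) - 1):
            raise ValueError(f"no level {level}")
        return bounds[level + 1] - bounds[level]

    def blocks_before_subsample(self, k: int) -> int:
        """Stride-1 blocks preceding the k-th (1-based) stride-2 block."""
        seen = 0
        count = 0
        for s in self.block_strides:
            if s == 2:
                seen += 1
                if seen == k:
                    return count
                count = 0
            else:
                count += 1
        raise ValueError(f"network has only {seen} stride-2 blocks")

    # execution -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.config.input_h or x.shape[3] != self.config.input_w:
            raise ValueError(
                f"expected {self.config.input_h}x{self.config.input_w} input, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        return self.net.forward(x.astype(self.params()[0].value.dtype, copy=False),
                                train=train)

    def feature_map(self, x: np.ndarray) -> np.ndarray:
        """Final pre-head feature map (for shape introspection/tests)."""
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        out = x.astype(self.params()[0].value.dtype, copy=False)
        for layer in self.net.layers:
            if isinstance(layer, (nn.GlobalAvgPool, nn.Flatten)):
                break
            out = layer.forward(out, train=False)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def params(self) -> list[nn.Param]:
        return self.net.params()

    # persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write weights (npz) plus a JSON sidecar describing the config."""
        path = Path(path)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for j, layer in enumerate(self.net.layers):
            if isinstance(layer, nn.BatchNorm2d):
                arrays[f"bn{j}_mean"] = layer.running_mean
                arrays[f"bn{j}_var"] = layer.running_var
        np.savez(path, **arrays)
        path.with_suffix(".json").write_text(self.config.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "Backbone":
        path = Path(path)
        config = BackboneConfig.from_json(path.with_suffix(".json").read_text())
        model = cls(config)
        npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        if not npz_path.exists():
            npz_path = path
        with np.load(npz_path) as data:
            for i, p in enumerate(model.params()):
                p.value = data[f"p{i}"]
                p.grad = np.zeros_like(p.value)
            for j, layer in enumerate(model.net.layers):
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean = data[f"bn{j}_mean"]
                    layer.running_var = data[f"bn{j}_var"]
        return model


def build(config: BackboneConfig, seed: int = 0, dtype=np.float32) -> Backbone:
    """Instantiate ``config`` with Xavier-uniform weights from ``seed``."""
    return Backbone(config, seed=seed, dtype=dtype)


# losses ------------------------------------------------------------------

def regression_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error between raw logits and normalized coordinates."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.mean(np.square(pred - target)))


def regression_loss_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return (2.0 / pred.size) * (pred - target)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def classification_loss(logits: np.ndarray, labels) -> float:
    """Softmax cross entropy, averaged over the batch (or a single sample)."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim == 1:
        logits = logits[None]
        labels = np.asarray([labels])
    else:
        labels = np.asarray(labels)
    if not np.all(np.isfinite(logits)):
        raise ValueError("logits must be finite")
    p = softmax(logits)
    eps = np.finfo(np.float64).tiny
    return float(-np.mean(np.log(p[np.arange(len(labels)), labels] + eps)))


def classification_loss_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    logits = np.asarray(logits)
    labels = np.asarray(labels)
    p = softmax(logits.astype(np.float64))
    p[np.arange(len(labels)), labels] -= 1.0
    return (p / len(labels)).astype(logits.dtype)
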