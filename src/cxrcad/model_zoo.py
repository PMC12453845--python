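"""Classifier builders and training.

The centerpiece is a compact five-block CNN for 256 x 256 single-channel
patches: each block is Conv2D (2x2 kernel, stride 2, ReLU) -> batch
normalization -> dropout(0.5), followed by non-overlapping 2x2 average
pooling, flatten, a fully connected fusion layer (width 128), the
two-class head and softmax. Counting the five convolutions, five batch
norms, five dropouts and the fully connected head gives the
architecture's 16-layer tally. Stride-2 convolutions carry the
downsampling (256 -> 128 -> 64 -> 32 -> 16 -> 8 -> pooled 4), keeping
the flattened feature vector small.

Standard baselines (AlexNet, GoogLeNet, ResNet-34) are built in their
published shapes, adapted only at the input (1 channel) and the class
head, for comparison runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import (
    AdaptiveAvgPool2d,
    AvgPool2d,
    BatchNorm2d,
    Branches,
    Conv2d,
    Dropout,
    Flatten,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ReLU,
    Residual,
    Sequential,
)
from .errors import GeometryError, ValidationError

BASELINES = ("alexnet", "googlenet", "resnet34")

LABEL_TO_INT = {"normal": 0, "cancer": 1}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


@dataclass(frozen=True)
class ModelConfig:
    """Declarative description of the custom CNN.

    ``block_filters`` are the five per-block channel widths (monotone
    widening by default); ``kernel`` is fixed at 2 by design;
    ``pooling`` selects the single pooling layer after the blocks:
    windowed non-overlapping 2x2 average pooling (default) or global
    average pooling.
    """

    input_size: int = 256
    block_filters: tuple[int, ...] = (32, 64, 96, 128, 160)
    kernel: int = 2
    block_stride: int = 2
    dropout_rate: float = 0.5
    pooling: str = "average"
    fusion_width: int = 128
    n_classes: int = 2

    def __post_init__(self) -> None:
        if len(self.block_filters) != 5:
            raise ValidationError("block_filters must list exactly 5 widths")
        if self.kernel != 2:
            raise ValidationError("the block kernel is fixed at 2")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.pooling not in ("average", "global"):
            raise ValidationError("pooling must be 'average' or 'global'")


@dataclass
class LayerInfo:
    name: str
    kind: str
    output_shape: tuple[int, ...]
    n_params: int


@dataclass
class ModelSpec:
    """A built, runnable classifier with its layer table.

    ``predict`` maps a batch of single-channel ``input_size`` squares to
    rows of class probabilities (softmax: non-negative, summing to 1).
    ``total_parameters`` counts trainable parameters only (conv/linear
    weights and biases, batch-norm scale and shift).
    """

    name: str
    network: Sequential
    input_size: int
    n_classes: int
    layers: list[LayerInfo] = field(default_factory=list)
    counted_layers: int = 0
    config: dict = field(default_factory=dict)

    @property
    def total_parameters(self) -> int:
        return self.network.n_params()

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class-probability rows for a batch of patches.

        ``x`` may be (N, H, W) or (N, 1, H, W). Inference is
        deterministic: dropout is inactive and batch norm uses running
        statistics.
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None, :, :]
        out = [
            _nn.softmax(self.network.forward(x[i : i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def summary(self) -> str:
        lines = [f"{self.name}: {self.total_parameters:,} parameters"]
        for li in self.layers:
            lines.append(f"  {li.name:<18} {li.kind:<14} {str(li.output_shape):<20} {li.n_params:>10,}")
        return "\n".join(lines)


def _trace(network: Sequential, input_size: int, names: list[str] | None = None) -> list[LayerInfo]:
    """Record every top-level layer's output shape and parameter count
    by forwarding a dummy batch, then append the softmax row."""
    x = np.zeros((1, 1, input_size, input_size), dtype=np.float32)
    table = []
    for i, layer in enumerate(network.layers):
        try:
            x = layer.forward(x, train=False)
        except GeometryError as exc:
            raise GeometryError(
                f"layer {i} ({type(layer).__name__}): {exc} — input_size {input_size} "
                "does not divide cleanly through the stride chain"
            ) from exc
        name = names[i] if names else f"layer{i}"
        table.append(LayerInfo(name, type(layer).__name__, tuple(x.shape[1:]), layer.n_params()))
    table.append(LayerInfo("softmax", "Softmax", tuple(x.shape[1:]), 0))
    return table


def build_custom_cnn(config: ModelConfig | None = None, seed: int = 0) -> ModelSpec:
    """Build the five-block custom CNN described in the module docstring.

    Raises :class:`GeometryError` (naming the failing layer) when
    ``input_size`` does not divide cleanly through the stride chain and
    final pooling.
    """
    config = config or ModelConfig()
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    names: list[str] = []
    c_in = 1
    for i, c_out in enumerate(config.block_filters, start=1):
        layers += [
            Conv2d(c_in, c_out, config.kernel, stride=config.block_stride,
                   padding="ceil", pad_mode="edge", rng=rng),
            ReLU(),
            BatchNorm2d(c_out),
            Dropout(config.dropout_rate),
        ]
        names += [f"conv{i}", f"relu{i}", f"bn{i}", f"dropout{i}"]
        c_in = c_out
    if config.pooling == "average":
        layers.append(AvgPool2d(2))
        names.append("avgpool")
    else:
        layers.append(GlobalAvgPool())
        names.append("globalpool")
    layers += [Flatten()]
    names += ["flatten"]

    # fusion width needs the flattened size: trace the feature stack once
    probe = Sequential(layers)
    feat = probe.forward(np.zeros((1, 1, config.input_size, config.input_size), dtype=np.float32))
    flat = feat.shape[1]
    layers += [
        Linear(flat, config.fusion_width, rng=rng),
        ReLU(),
        Linear(config.fusion_width, config.n_classes, rng=rng),
    ]
    names += ["fusion", "fusion_relu", "fc_head"]

    network = Sequential(layers)
    table = _trace(network, config.input_size, names)
    n_conv = sum(isinstance(l, Conv2d) for l in network.walk())
    n_bn = sum(isinstance(l, BatchNorm2d) for l in network.walk())
    n_drop = sum(isinstance(l, Dropout) for l in network.walk())
    counted = n_conv + n_bn + n_drop + 1  # + the fully connected head
    return ModelSpec(
        name="custom_cnn",
        network=network,
        input_size=config.input_size,
        n_classes=config.n_classes,
        layers=table,
        counted_layers=counted,
        config=config.__dict__.copy(),
    )


def _conv_bn_relu(c_in, c_out, k, rng, stride=1, padding=0) -> list[_nn.Layer]:
    return [Conv2d(c_in, c_out, k, stride=stride, padding=padding, rng=rng),
            BatchNorm2d(c_out), ReLU()]


def _alexnet(input_size: int, n_classes: int, rng) -> tuple[Sequential, int]:
    layers = [
        Conv2d(1, 64, 11, stride=4, padding=2, rng=rng), ReLU(), MaxPool2d(3, 2),
        Conv2d(64, 192, 5, padding=2, rng=rng), ReLU(), MaxPool2d(3, 2),
        Conv2d(192, 384, 3, padding=1, rng=rng), ReLU(),
        Conv2d(384, 256, 3, padding=1, rng=rng), ReLU(),
        Conv2d(256, 256, 3, padding=1, rng=rng), ReLU(), MaxPool2d(3, 2),
        AdaptiveAvgPool2d(6), Flatten(),
        Dropout(0.5), Linear(256 * 36, 4096, rng=rng), ReLU(),
        Dropout(0.5), Linear(4096, 4096, rng=rng), ReLU(),
        Linear(4096, n_classes, rng=rng),
    ]
    return Sequential(layers), 8  # 5 conv + 3 FC


def _inception(c_in, c1, c3r, c3, c5r, c5, cp, rng) -> Branches:
    return Branches([
        Sequential(_conv_bn_relu(c_in, c1, 1, rng)),
        Sequential(_conv_bn_relu(c_in, c3r, 1, rng) + _conv_bn_relu(c3r, c3, 3, rng, padding=1)),
        Sequential(_conv_bn_relu(c_in, c5r, 1, rng) + _conv_bn_relu(c5r, c5, 3, rng, padding=1)),
        Sequential([MaxPool2d(3, 1, padding=1)] + _conv_bn_relu(c_in, cp, 1, rng)),
    ])


def _googlenet(input_size: int, n_classes: int, rng) -> tuple[Sequential, int]:
    layers = (
        _conv_bn_relu(1, 64, 7, rng, stride=2, padding=3)
        + [MaxPool2d(3, 2, padding="ceil")]
        + _conv_bn_relu(64, 64, 1, rng)
        + _conv_bn_relu(64, 192, 3, rng, padding=1)
        + [MaxPool2d(3, 2, padding="ceil")]
        + [
            _inception(192, 64, 96, 128, 16, 32, 32, rng),
            _inception(256, 128, 128, 192, 32, 96, 64, rng),
            MaxPool2d(3, 2, padding="ceil"),
            _inception(480, 192, 96, 208, 16, 48, 64, rng),
            _inception(512, 160, 112, 224, 24, 64, 64, rng),
            _inception(512, 128, 128, 256, 24, 64, 64, rng),
            _inception(512, 112, 144, 288, 32, 64, 64, rng),
            _inception(528, 256, 160, 320, 32, 128, 128, rng),
            MaxPool2d(3, 2, padding="ceil"),
            _inception(832, 256, 160, 320, 32, 128, 128, rng),
            _inception(832, 384, 192, 384, 48, 128, 128, rng),
            GlobalAvgPool(),
            Flatten(),
            Dropout(0.4),
            Linear(1024, n_classes, rng=rng),
        ]
    )
    # depth convention: 3 stem convs + 2 conv stages per inception module + 1 FC
    return Sequential(layers), 3 + 2 * 9 + 1


def _basic_block(c_in, c_out, stride, rng) -> Residual:
    body = Sequential(
        _conv_bn_relu(c_in, c_out, 3, rng, stride=stride, padding=1)
        + [Conv2d(c_out, c_out, 3, padding=1, rng=rng), BatchNorm2d(c_out)]
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Sequential(
            [Conv2d(c_in, c_out, 1, stride=stride, rng=rng), BatchNorm2d(c_out)]
        )
    return Residual(body, shortcut)


def _resnet34(input_size: int, n_classes: int, rng) -> tuple[Sequential, int]:
    layers: list[_nn.Layer] = _conv_bn_relu(1, 64, 7, rng, stride=2, padding=3)
    layers.append(MaxPool2d(3, 2, padding=1))
    c_in = 64
    for c_out, blocks, stride in ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)):
        for b in range(blocks):
            layers.append(_basic_block(c_in, c_out, stride if b == 0 else 1, rng))
            c_in = c_out
    layers += [GlobalAvgPool(), Flatten(), Linear(512, n_classes, rng=rng)]
    # 1 stem conv + 2 convs per basic block (downsample 1x1s uncounted) + 1 FC
    return Sequential(layers), 1 + 2 * (3 + 4 + 6 + 3) + 1


def build_baseline(name: str, input_size: int = 256, n_classes: int = 2, seed: int = 0) -> ModelSpec:
    """Build a published baseline adapted to 1-channel input.

    ``name`` is one of ``alexnet`` (8 layers: 5 conv + 3 FC),
    ``googlenet`` (22-layer inception network) or ``resnet34``
    (34 weighted layers with residual shortcuts).
    """
    rng = np.random.default_rng(seed)
    builders = {"alexnet": _alexnet, "googlenet": _googlenet, "resnet34": _resnet34}
    if name not in builders:
        raise ValidationError(f"unknown baseline {name!r}; valid names: {sorted(builders)}")
    network, counted = builders[name](input_size, n_classes, rng)
    table = _trace(network, input_size)
    return ModelSpec(
        name=name,
        network=network,
        input_size=input_size,
        n_classes=n_classes,
        layers=table,
        counted_layers=counted,
        config={"name": name, "input_size": input_size, "n_classes": n_classes},
    )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (the published description leaves the
    optimizer unstated; Adam at 1e-3 with batch 32 is the default and
    everything is configurable). ``lr_decay`` multiplies the learning
    rate once at ``decay_epoch`` (1.0 disables); ``weight_decay`` is
    decoupled L2 shrinkage applied to conv/linear weights."""

    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    weight_decay: float = 0.0
    lr_decay: float = 1.0
    decay_epoch: int | None = None
    ema_decay: float = 0.0  # >0 enables Polyak weight averaging for inference
    cancer_weight: float = 1.0  # loss weight of the positive (cancer) class


def _as_int_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return np.array([LABEL_TO_INT[str(v).lower()] for v in y], dtype=np.int64)
    return y.astype(np.int64)


def train_classifier(
    model: ModelSpec,
    x: np.ndarray,
    y,
    hyper: TrainConfig | None = None,
    x_val: np.ndarray | None = None,
    y_val=None,
) -> tuple[ModelSpec, list[dict]]:
    """Train ``model`` by minimizing two-class cross-entropy.

    Deterministic given ``hyper.seed`` and the data order: the same
    seed, data and model initialization reproduce the loss trajectory
    exactly. Returns the (mutated) model and a per-epoch history of
    loss/accuracy, with validation columns when a held-out set is given.
    """
    hyper = hyper or TrainConfig()
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 3:
        x = x[:, None, :, :]
    y = _as_int_labels(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain at least one example per class")
    rng = np.random.default_rng(hyper.seed)
    opt = _nn.Adam(model.network, lr=hyper.learning_rate, weight_decay=hyper.weight_decay)
    history = []
    n = x.shape[0]
    ema = None
    if hyper.ema_decay > 0:
        ema = [
            {k: v.copy() for k, v in layer.params.items()}
            for layer in model.network.walk()
        ]
    for epoch in range(1, hyper.epochs + 1):
        if hyper.decay_epoch is not None and epoch == hyper.decay_epoch:
            opt.lr *= hyper.lr_decay
        perm = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, hyper.batch_size):
            idx = perm[start : start + hyper.batch_size]
            xb, yb = x[idx], y[idx]
            logits = model.network.forward(xb, train=True, rng=rng)
            weights = None
            if hyper.cancer_weight != 1.0:
                weights = np.where(yb == 1, hyper.cancer_weight, 1.0)
            loss, dlogits = _nn.softmax_cross_entropy(logits, yb, weights)
            model.network.backward(dlogits)
            opt.step()
            if ema is not None:
                d = hyper.ema_decay
                for slot, layer in zip(ema, model.network.walk()):
                    for k, v in layer.params.items():
                        slot[k] *= d
                        slot[k] += (1 - d) * v
            losses.append(loss * len(idx))
            hits += int((logits.argmax(axis=1) == yb).sum())
        row = {"epoch": epoch, "loss": sum(losses) / n, "acc": hits / n}
        if x_val is not None:
            probs = model.predict(x_val)
            yv = _as_int_labels(y_val)
            row["val_loss"] = float(-np.log(np.clip(probs[np.arange(len(yv)), yv], 1e-12, None)).mean())
            row["val_acc"] = float((probs.argmax(axis=1) == yv).mean())
        history.append(row)
    if ema is not None:
        for slot, layer in zip(ema, model.network.walk()):
            for k in layer.params:
                layer.params[k][...] = slot[k]
    # make inference statistics consistent with the final weights
    _nn.recalibrate_batchnorm(model.network, x)
    return model, history


def save_model(spec: ModelSpec, path) -> None:
    """Serialize weights + config into a single ``.npz`` checkpoint."""
    arrays = {}
    for i, layer in enumerate(spec.network.walk()):
        for key, val in layer.params.items():
            arrays[f"p{i}:{key}"] = val
        if isinstance(layer, BatchNorm2d):
            arrays[f"p{i}:running_mean"] = layer.running_mean
            arrays[f"p{i}:running_var"] = layer.running_var
    meta = {"name": spec.name, "config": spec.config}
    np.savez(Path(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> ModelSpec:
    """Rebuild a checkpointed model and restore its weights."""
    data = np.load(Path(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    if meta["name"] == "custom_cnn":
        cfg = meta["config"]
        cfg["block_filters"] = tuple(cfg["block_filters"])
        spec = build_custom_cnn(ModelConfig(**cfg))
    else:
        cfg = meta["config"]
        spec = build_baseline(cfg["name"], cfg["input_size"], cfg["n_classes"])
    for i, layer in enumerate(spec.network.walk()):
        for key in layer.params:
            layer.params[key][...] = data[f"p{i}:{key}"]
        if isinstance(layer, BatchNorm2d):
            layer.running_mean[...] = data[f"p{i}:running_mean"]
            layer.running_var[...] = data[f"p{i}:running_var"]
    return spec
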