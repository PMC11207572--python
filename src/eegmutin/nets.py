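"""Declarative builders for the two compact EEG classifiers.

A :class:`ModelGraph` is an ordered list of :class:`LayerSpec` entries with
shapes chained from the input, close in spirit to a Keras ``summary()``:
every layer's output shape and parameter count are computable from its
hyperparameters alone, which makes the architecture auditable without
instantiating any weights.  Array layout is channels-last.

The two builders produce:

* an EEGNet-style compact CNN — temporal convolution (8 filters, kernel
  length 40), depthwise spatial convolution (depth multiplier 10),
  separable convolution (depthwise length 16 + 80 pointwise filters), all
  bias-free, batch-normalized, ELU-activated, average-pooled 4 then 8,
  dropout 0.2, and a dense softmax head — 54,632 parameters at the default
  54 x 440 input;
* a hybrid CNN-LSTM — three length-3 1-D convolutions (128/64/64 filters,
  with bias), leaky-ReLU (slope 0.005) activations, max-pool 2, LSTM
  layers of 64 (sequence output) and 32 (final state) units, and dense
  layers of 54 and ``n_classes`` units — 107,278 parameters at default.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Any, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# activation functions

def elu(x, alpha: float = 1.0):
    """Exponential linear unit: x for x >= 0, alpha*(e^x - 1) otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, alpha * np.expm1(x))


def leaky_relu(x, alpha: float = 0.005):
    """Leaky ReLU: alpha*x for x < 0, x otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, alpha * x, x)


def softmax(x, axis: int = -1):
    """Overflow-safe softmax along ``axis`` (max-shifted)."""
    x = np.asarray(x, dtype=float)
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# layer specifications

class UnsupportedLayerError(ValueError):
    pass


class ShapeError(ValueError):
    pass


#: Supported layer kinds and the hyperparameter keys each understands.
_KINDS = {
    "input", "conv2d_temporal", "depthwise_conv2d", "separable_conv2d",
    "conv1d", "lstm", "batch_norm", "avg_pool2d", "max_pool1d",
    "dropout", "flatten", "dense", "activation", "softmax",
}


@dataclasses.dataclass
class LayerSpec:
    """One layer: kind, hyperparameters, and its declared output shape."""

    name: str
    kind: str
    params: dict[str, Any]
    output_shape: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise UnsupportedLayerError(f"unknown layer kind {self.kind!r}")


def _infer(kind: str, p: dict, in_shape: tuple[int, ...]) -> tuple[int, ...]:
    """Output shape of a layer from its hyperparameters and input shape."""
    if kind == "input":
        return tuple(p["shape"])
    if kind == "conv2d_temporal":
        h, w, _ = in_shape
        return (h, w, p["filters"])                      # same padding on W
    if kind == "depthwise_conv2d":
        h, w, c = in_shape
        if p["kernel_h"] != h:
            raise ShapeError(
                f"depthwise kernel height {p['kernel_h']} != input height {h}"
            )
        return (1, w, c * p["depth_multiplier"])          # valid padding
    if kind == "separable_conv2d":
        h, w, _ = in_shape
        return (h, w, p["filters"])                      # same padding on W
    if kind == "conv1d":
        t, _ = in_shape
        return (t, p["filters"])                         # same padding
    if kind == "lstm":
        t, _ = in_shape
        return (t, p["units"]) if p["return_sequences"] else (p["units"],)
    if kind == "batch_norm":
        return in_shape
    if kind == "avg_pool2d":
        h, w, c = in_shape
        out_w = w // p["pool"]
        if out_w < 1:
            raise ShapeError(f"pooling {p['pool']} underflows width {w}")
        return (h, out_w, c)
    if kind == "max_pool1d":
        t, c = in_shape
        out_t = t // p["pool"]
        if out_t < 1:
            raise ShapeError(f"pooling {p['pool']} underflows length {t}")
        return (out_t, c)
    if kind in ("dropout", "activation", "softmax"):
        return in_shape
    if kind == "flatten":
        return (int(np.prod(in_shape)),)
    if kind == "dense":
        return (p["units"],)
    raise UnsupportedLayerError(kind)


def _count(kind: str, p: dict, in_shape: tuple[int, ...]) -> int:
    """Trainable + batch-norm statistic parameter count of one layer.

    Batch normalization contributes 4 per feature (scale, shift, running
    mean, running variance); convolution and dense layers include a bias
    term iff their ``use_bias`` flag is set.
    """
    if kind in ("input", "dropout", "activation", "softmax", "flatten",
                "avg_pool2d", "max_pool1d"):
        return 0
    if kind == "conv2d_temporal":
        _, _, c = in_shape
        n = p["kernel_w"] * c * p["filters"]
        return n + (p["filters"] if p["use_bias"] else 0)
    if kind == "depthwise_conv2d":
        _, _, c = in_shape
        n = p["kernel_h"] * c * p["depth_multiplier"]
        return n + (c * p["depth_multiplier"] if p["use_bias"] else 0)
    if kind == "separable_conv2d":
        _, _, c = in_shape
        n = c * p["kernel_w"] + c * p["filters"]
        return n + (p["filters"] if p["use_bias"] else 0)
    if kind == "conv1d":
        _, c = in_shape
        n = p["kernel"] * c * p["filters"]
        return n + (p["filters"] if p["use_bias"] else 0)
    if kind == "lstm":
        c = in_shape[-1]
        u = p["units"]
        return 4 * ((c + u) * u + u)
    if kind == "batch_norm":
        return 4 * in_shape[-1]
    if kind == "dense":
        n = in_shape[0] * p["units"]
        return n + (p["units"] if p["use_bias"] else 0)
    raise UnsupportedLayerError(kind)


@dataclasses.dataclass
class ModelGraph:
    """Ordered layer chain with consistent shapes."""

    name: str
    layers: list[LayerSpec]
    n_classes: int

    @property
    def input_shape(self) -> tuple[int, ...]:
        return self.layers[0].output_shape

    def validate(self) -> None:
        """Recompute every shape from hyperparameters and compare."""
        shape = self.layers[0].output_shape
        for spec in self.layers[1:]:
            shape = _infer(spec.kind, spec.params, shape)
            if tuple(spec.output_shape) != tuple(shape):
                raise ShapeError(
                    f"{spec.name}: declared {spec.output_shape}, "
                    f"recomputed {shape}"
                )
        if shape != (self.n_classes,):
            raise ShapeError(
                f"final shape {shape} does not emit {self.n_classes} classes"
            )

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name, "n_classes": self.n_classes,
            "layers": [dataclasses.asdict(s) for s in self.layers],
        }, indent=1)

    def summary(self) -> str:
        """Tabular report in the familiar layer / shape / parameters form."""
        per_layer, total = count_parameters(self)
        lines = [f"Model: {self.name}",
                 f"{'Layer (type)':<28}{'Output Shape':<20}{'Params':>10}"]
        for spec, n in zip(self.layers, per_layer):
            shape = "(None, " + ", ".join(str(d) for d in spec.output_shape) + ")"
            lines.append(f"{spec.name:<28}{shape:<20}{n:>10,}")
        lines.append(f"Total parameters: {total:,}")
        return "\n".join(lines)


def count_parameters(g: ModelGraph) -> tuple[list[int], int]:
    """Per-layer parameter counts (recomputed from hyperparameters) + total."""
    counts = []
    shape = g.layers[0].output_shape
    for i, spec in enumerate(g.layers):
        if i == 0:
            counts.append(0)
            continue
        counts.append(_count(spec.kind, spec.params, shape))
        shape = _infer(spec.kind, spec.params, shape)
    return counts, int(sum(counts))


# ---------------------------------------------------------------------------
# builders

def _chain(name: str, n_classes: int,
           steps: Sequence[tuple[str, str, dict]]) -> ModelGraph:
    layers: list[LayerSpec] = []
    shape: tuple[int, ...] | None = None
    for lname, kind, params in steps:
        shape = _infer(kind, params, shape if shape is not None else ())
        layers.append(LayerSpec(lname, kind, params, shape))
    g = ModelGraph(name, layers, n_classes)
    g.validate()
    return g


def build_eegnet(chans: int = 54, samples: int = 440,
                 n_classes: int = 40, f1: int = 8, depth: int = 10,
                 kernel_length: int = 40, dropout: float = 0.2) -> ModelGraph:
    """EEGNet-style compact CNN over a ``(chans, samples, 1)`` input.

    Temporal filters learn frequency content, the depthwise stage learns
    per-filter spatial patterns over all channels, and the separable stage
    mixes the resulting feature maps; F2 = F1 * depth pointwise filters.
    """
    if chans < 1 or samples < 32:
        raise ShapeError("need chans >= 1 and samples >= 32 (pooling footprint)")
    f2 = f1 * depth
    steps = [
        ("Input", "input", {"shape": (chans, samples, 1)}),
        ("Conv2D", "conv2d_temporal",
         {"filters": f1, "kernel_w": kernel_length, "use_bias": False}),
        ("Batch_normalization_1", "batch_norm", {}),
        ("Depthwise_conv2D", "depthwise_conv2d",
         {"kernel_h": chans, "depth_multiplier": depth, "use_bias": False}),
        ("Batch_normalization_2", "batch_norm", {}),
        ("Activation_1", "activation", {"fn": "elu", "alpha": 1.0}),
        ("Average_pooling2D_1", "avg_pool2d", {"pool": 4}),
        ("Dropout_1", "dropout", {"rate": dropout}),
        ("Separable_conv2D", "separable_conv2d",
         {"kernel_w": 16, "filters": f2, "use_bias": False}),
        ("Batch_normalization_3", "batch_norm", {}),
        ("Activation_2", "activation", {"fn": "elu", "alpha": 1.0}),
        ("Average_pooling2D_2", "avg_pool2d", {"pool": 8}),
        ("Dropout_2", "dropout", {"rate": dropout}),
        ("Flatten", "flatten", {}),
        ("Dense", "dense", {"units": n_classes, "use_bias": True}),
        ("Softmax", "softmax", {}),
    ]
    return _chain("EEGNet", n_classes, steps)


def build_cnn_lstm(chans: int = 54, samples: int = 440,
                   n_classes: int = 40, dropout: float = 0.2,
                   leak: float = 0.005) -> ModelGraph:
    """Hybrid CNN-LSTM over a ``(samples, chans)`` input sequence."""
    if chans < 1 or samples < 4:
        raise ShapeError("need chans >= 1 and samples >= 4")
    steps = [
        ("Input", "input", {"shape": (samples, chans)}),
        ("Conv1D_layer1", "conv1d",
         {"filters": 128, "kernel": 3, "use_bias": True}),
        ("Dropout_1", "dropout", {"rate": dropout}),
        ("Activation_1", "activation", {"fn": "leaky_relu", "alpha": leak}),
        ("Max_Pooling", "max_pool1d", {"pool": 2}),
        ("Conv1D_layer2", "conv1d",
         {"filters": 64, "kernel": 3, "use_bias": True}),
        ("Dropout_2", "dropout", {"rate": dropout}),
        ("Activation_2", "activation", {"fn": "leaky_relu", "alpha": leak}),
        ("LSTM_layer1", "lstm", {"units": 64, "return_sequences": True}),
        ("Conv1D_layer3", "conv1d",
         {"filters": 64, "kernel": 3, "use_bias": True}),
        ("Dropout_3", "dropout", {"rate": dropout}),
        ("Activation_3", "activation", {"fn": "leaky_relu", "alpha": leak}),
        ("LSTM_layer2", "lstm", {"units": 32, "return_sequences": False}),
        ("Dropout_4", "dropout", {"rate": dropout}),
        ("Dense_1", "dense", {"units": 54, "use_bias": True}),
        ("Activation_4", "activation", {"fn": "leaky_relu", "alpha": leak}),
        ("Dense_2", "dense", {"units": n_classes, "use_bias": True}),
        ("Softmax", "softmax", {}),
    ]
    return _chain("CNN-LSTM", n_classes, steps)
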