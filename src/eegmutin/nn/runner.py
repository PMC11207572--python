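"""Compile a declarative :class:`~eegmutin.nets.ModelGraph` into runnable
numpy layers and drive forward/backward passes.

The trailing softmax is folded into the categorical cross-entropy loss
(the usual numerically stable pairing); ``predict_proba`` applies it
explicitly.
"""

from __future__ import annotations

import numpy as np

from ..nets import ModelGraph, softmax
from . import layers as L


class NadamOptimizer:
    """Adam with Nesterov momentum (the 'Nadam' update).

    Applies the bias-corrected first moment blended with the current
    gradient, so the lookahead step uses momentum one iteration ahead.
    """

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = b1 * (m / c1) + (1 - b1) * (g / c1)
            v_hat = v / c2
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


def compile_graph(graph: ModelGraph, rng: np.random.Generator) -> list[L.Layer]:
    """Instantiate executable layers for every spec in the graph.

    The final softmax becomes an identity here (handled by the loss); the
    declared input layer has no runtime counterpart.
    """
    out: list[L.Layer] = []
    shape = graph.layers[0].output_shape
    for spec in graph.layers[1:]:
        p = spec.params
        if spec.kind == "conv2d_temporal":
            out.append(L.TemporalConv2D(rng, shape[-1], p["filters"],
                                        p["kernel_w"], p["use_bias"]))
        elif spec.kind == "depthwise_conv2d":
            out.append(L.DepthwiseSpatialConv2D(rng, shape[0], shape[-1],
                                                p["depth_multiplier"]))
        elif spec.kind == "separable_conv2d":
            out.append(L.SeparableTemporalConv2D(rng, shape[-1], p["filters"],
                                                 p["kernel_w"]))
        elif spec.kind == "conv1d":
            out.append(L.Conv1D(rng, shape[-1], p["filters"], p["kernel"],
                                p["use_bias"]))
        elif spec.kind == "lstm":
            out.append(L.LSTM(rng, shape[-1], p["units"],
                              p["return_sequences"]))
        elif spec.kind == "batch_norm":
            out.append(L.BatchNorm(shape[-1]))
        elif spec.kind == "avg_pool2d":
            out.append(L.AvgPoolW(p["pool"]))
        elif spec.kind == "max_pool1d":
            out.append(L.MaxPool1D(p["pool"]))
        elif spec.kind == "dropout":
            out.append(L.Dropout(p["rate"], rng))
        elif spec.kind == "flatten":
            out.append(L.Flatten())
        elif spec.kind == "dense":
            out.append(L.Dense(rng, shape[0], p["units"], p["use_bias"]))
        elif spec.kind == "activation":
            if p["fn"] == "elu":
                out.append(L.ELU(p.get("alpha", 1.0)))
            elif p["fn"] == "leaky_relu":
                out.append(L.LeakyReLU(p.get("alpha", 0.005)))
            else:
                raise ValueError(f"unknown activation {p['fn']!r}")
        elif spec.kind == "softmax":
            out.append(L.Layer())    # folded into the loss
        else:
            raise ValueError(f"cannot compile layer kind {spec.kind!r}")
        shape = spec.output_shape
    return out


class Network:
    """Executable network: compiled layers plus the graph they came from."""

    def __init__(self, graph: ModelGraph, seed: int = 0):
        graph.validate()
        self.graph = graph
        self.rng = np.random.default_rng([seed & 0x7FFFFFFF, 31337])
        self.layers = compile_graph(graph, self.rng)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward_logits(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x.astype(np.float32)
        for layer in self.layers:
            h = layer.forward(h, training)
        return h

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = dlogits.astype(np.float32)
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for lo in range(0, x.shape[0], batch_size):
            logits = self.forward_logits(x[lo:lo + batch_size], training=False)
            out.append(softmax(logits, axis=-1))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=-1)


def cross_entropy_and_grad(logits: np.ndarray,
                           onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient at the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = logits.shape[0]
    loss = float(-(onehot * logp).sum() / n)
    grad = (np.exp(logp) - onehot) / n
    return loss, grad.astype(np.float32)
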