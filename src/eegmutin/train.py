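"""Training contract, cross-validation protocols, and metrics.

Training minimizes categorical cross-entropy with the Nadam optimizer
under a triangular cyclical learning rate (CLR) oscillating between
``clr_low`` and ``clr_high`` with a half-period of
``clr_step_multiplier`` x iterations-per-epoch.  Evaluation protocols are
shuffled k-fold over segments and round-robin leave-one-subject-out
(LOSOV); accuracy follows the one-vs-rest (TP+TN)/(TP+TN+FP+FN)
convention per class, plus the usual multiclass trace/total.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Literal, Sequence

import numpy as np

from .dataset import SegmentSet
from .nets import ModelGraph, build_cnn_lstm, build_eegnet
from .nn import Network, NadamOptimizer, cross_entropy_and_grad
from .preprocess import (EpochArray, PreprocessConfig, apply_scaler,
                         fit_scaler, make_epochs, preprocess)


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings; full-scale defaults, with a desk preset.

    The published regime is 1000 epochs at batch size 440; ``desk()``
    returns the reduced 30-epoch configuration used for CPU-scale runs.
    """

    epochs: int = 1000
    batch_size: int = 440
    clr_low: float = 1e-7
    clr_high: float = 1e-3
    clr_step_multiplier: int = 8
    optimizer: str = "nadam"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.clr_low < self.clr_high:
            raise ValueError("need 0 < clr_low < clr_high")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def desk(cls, **kw) -> "TrainConfig":
        """Reduced CPU-scale preset: 30 epochs, small mini-batches (better
        cache locality and more optimizer steps at small sample counts)."""
        kw.setdefault("epochs", 30)
        kw.setdefault("batch_size", 64)
        return cls(**kw)


def clr_schedule(iteration: int, cfg: TrainConfig,
                 steps_per_epoch: int = 1) -> float:
    """Triangular CLR: low at iteration 0, high at the half-period s,
    back to low at 2s, period 2s, with s = multiplier * steps_per_epoch."""
    s = cfg.clr_step_multiplier * steps_per_epoch
    cycle = np.floor(1 + iteration / (2 * s))
    x = abs(iteration / s - 2 * cycle + 1)
    return cfg.clr_low + (cfg.clr_high - cfg.clr_low) * max(0.0, 1.0 - x)


@dataclasses.dataclass
class TrainedModel:
    network: Network
    loss_history: list[float]
    config: TrainConfig

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.network.predict(x)


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"labels outside [0, {n_classes}): "
            f"[{labels.min()}, {labels.max()}]"
        )
    eye = np.eye(n_classes, dtype=np.float32)
    return eye[labels]


def epochs_to_input(epochs: EpochArray, graph: ModelGraph) -> np.ndarray:
    """Orient an epoch array for a model: EEGNet wants (N, C, T, 1);
    the CNN-LSTM wants the (N, T, C) sequence layout."""
    if graph.layers[0].output_shape[-1] == 1:        # (chans, samples, 1)
        return epochs.data[:, :, :, None].astype(np.float32)
    return epochs.data.transpose(0, 2, 1).astype(np.float32)


def train(graph: ModelGraph, train_epochs: EpochArray,
          cfg: TrainConfig) -> TrainedModel:
    """Mini-batch training under the CLR schedule; deterministic per seed."""
    x = epochs_to_input(train_epochs, graph)
    y = _one_hot(train_epochs.labels, graph.n_classes)
    n = x.shape[0]
    net = Network(graph, seed=cfg.seed)
    opt = NadamOptimizer(net.params())
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 271828])
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    history: list[float] = []
    it = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits = net.forward_logits(x[idx], training=True)
            loss, dlogits = cross_entropy_and_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            net.backward(dlogits)
            opt.step(net.grads(), clr_schedule(it, cfg, steps_per_epoch))
            losses.append(loss)
            it += 1
        history.append(float(np.mean(losses)))
    return TrainedModel(net, history, cfg)


# ---------------------------------------------------------------------------
# split protocols

def kfold_split(n: int, k: int = 10, seed: int = 0,
                labels: np.ndarray | None = None) -> list[
                    tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition; fold sizes differ by at most one.

    With ``labels`` given, folds are stratified per class; default is a
    plain shuffle.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 1729])
    if labels is None:
        perm = rng.permutation(n)
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        folds = np.split(perm, np.cumsum(sizes)[:-1])
    else:
        folds_lists: list[list[int]] = [[] for _ in range(k)]
        labels = np.asarray(labels)
        pos = 0
        for c in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == c))
            for i, v in enumerate(idx):
                folds_lists[(pos + i) % k].append(v)
            pos += len(idx)
        folds = [np.asarray(sorted(f)) for f in folds_lists]
    out = []
    all_idx = np.arange(n)
    for f in folds:
        test = np.sort(f)
        out.append((np.setdiff1d(all_idx, test), test))
    return out


def losov_split(subjects: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Round-robin leave-one-subject-out rounds.

    One round per subject; round order follows the published rotation
    (the last subject ID is held out first, then 1, 2, ...).
    """
    subjects = np.asarray(subjects)
    ids = np.unique(subjects)
    if len(ids) < 2:
        raise ValueError("need at least 2 distinct subjects")
    order = np.roll(ids, 1)
    rounds = []
    for sid in order:
        test = np.flatnonzero(subjects == sid)
        train_idx = np.flatnonzero(subjects != sid)
        rounds.append((train_idx, test))
    return rounds


# ---------------------------------------------------------------------------
# metrics

@dataclasses.dataclass
class ConfusionMatrix:
    counts: np.ndarray      # (n_classes, n_classes), true x predicted

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(true_labels: Sequence[int], predicted_labels: Sequence[int],
                     n_classes: int) -> ConfusionMatrix:
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if len(t) and (min(t.min(), p.min()) < 0
                   or max(t.max(), p.max()) >= n_classes):
        raise ValueError("labels outside range")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def accuracy(cm: ConfusionMatrix, label: int | None = None) -> float:
    """Percent accuracy from a confusion matrix.

    With ``label`` given, the one-vs-rest form (TP+TN)/(TP+TN+FP+FN)*100
    for that class; otherwise overall multiclass accuracy trace/total*100.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts
    if label is None:
        return float(np.trace(c) / cm.total * 100.0)
    tp = c[label, label]
    fn = c[label].sum() - tp
    fp = c[:, label].sum() - tp
    tn = cm.total - tp - fn - fp
    return float((tp + tn) / cm.total * 100.0)


def per_class_diagonal(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal fraction per class (recall), as percentages."""
    row = cm.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.diag(cm.counts) / np.where(row == 0, 1, row)
    return d * 100.0


@dataclasses.dataclass
class EvalReport:
    """Fold-wise accuracies, their mean, and per-fold confusion matrices."""

    scheme: str
    model: str
    window: tuple[int, int]
    fold_accuracies: list[float]
    confusions: list[ConfusionMatrix]
    split_sizes: list[tuple[int, int]]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme, "model": self.model,
            "window": list(self.window),
            "fold_accuracies": self.fold_accuracies,
            "mean_accuracy": self.mean_accuracy,
            "split_sizes": self.split_sizes,
        }


# ---------------------------------------------------------------------------
# end-to-end protocol

ModelKind = Literal["eegnet", "cnn_lstm"]


def build_model(kind: ModelKind, chans: int, samples: int,
                n_classes: int) -> ModelGraph:
    if kind == "eegnet":
        return build_eegnet(chans=chans, samples=samples, n_classes=n_classes)
    if kind == "cnn_lstm":
        return build_cnn_lstm(chans=chans, samples=samples,
                              n_classes=n_classes)
    raise ValueError(f"unknown model kind {kind!r}")


def evaluate_protocol(
    ds: SegmentSet,
    model_kind: ModelKind = "eegnet",
    window: tuple[int, int] | None = None,
    scheme: Literal["kfold", "losov"] = "kfold",
    cfg: TrainConfig | None = None,
    k: int = 10,
    preprocess_cfg: PreprocessConfig | None = None,
    use_scaler: bool = True,
    scaler_hook: Callable | None = None,
) -> EvalReport:
    """Preprocess, split, train and score one model under one protocol.

    The standardizing scaler is fitted on each split's training fold only
    and applied unchanged to its test fold; ``use_scaler=False`` bypasses
    the stage entirely (the ablation arm).  ``scaler_hook(train_idx,
    test_idx, stats)`` is called per split for leakage auditing.
    """
    cfg = cfg or TrainConfig.desk()
    epochs, _report = preprocess(ds, preprocess_cfg, window)
    n = epochs.n_epochs
    if scheme == "kfold":
        splits = kfold_split(n, k=k, seed=cfg.seed)
    elif scheme == "losov":
        splits = losov_split(epochs.subjects)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    graph = build_model(model_kind, epochs.n_channels, epochs.data.shape[2],
                        ds.n_classes)
    fold_acc, confusions, sizes = [], [], []
    for fold, (tr, te) in enumerate(splits):
        tr_ep = EpochArray(epochs.data[tr], epochs.labels[tr],
                           epochs.subjects[tr], list(epochs.channel_names),
                           epochs.window_ms)
        te_ep = EpochArray(epochs.data[te], epochs.labels[te],
                           epochs.subjects[te], list(epochs.channel_names),
                           epochs.window_ms)
        if use_scaler:
            stats = fit_scaler(tr_ep)
            if scaler_hook is not None:
                scaler_hook(tr, te, stats)
            tr_ep = apply_scaler(tr_ep, stats)
            te_ep = apply_scaler(te_ep, stats)
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + fold)
        try:
            model = train(graph, tr_ep, fold_cfg)
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        pred = model.predict(epochs_to_input(te_ep, graph))
        cm = confusion_matrix(te_ep.labels, pred, ds.n_classes)
        fold_acc.append(accuracy(cm))
        confusions.append(cm)
        sizes.append((len(tr), len(te)))
    return EvalReport(
        scheme=scheme, model=model_kind,
        window=epochs.window_ms, fold_accuracies=fold_acc,
        confusions=confusions, split_sizes=sizes,
    )
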