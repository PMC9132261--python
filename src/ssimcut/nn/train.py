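"""Minibatch training: Adam, categorical cross-entropy, light augmentation.

Augmentation follows common practice for plant images — random horizontal /
vertical flips, zoom, and shear — applied to one extra batch per epoch rather
than to every batch, keeping single-CPU epochs fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .network import Network

__all__ = ["TrainConfig", "TrainResult", "Adam", "train", "evaluate",
           "softmax_cross_entropy"]


@dataclass
class TrainConfig:
    epochs: int = 1
    minibatch: int = 16
    learning_rate: float = 1e-3
    augment: bool = True
    zoom: bool = True
    flip: bool = True
    shear: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainResult:
    train_accuracy: list[float]  # per-epoch, percent
    test_accuracy: list[float]
    val_accuracy: list[float]
    best_epoch: int  # 1-based epoch of maximum test accuracy

    def history_rows(self):
        for e, (tr, te, va) in enumerate(
            zip(self.train_accuracy, self.test_accuracy, self.val_accuracy), start=1
        ):
            yield {"epoch": e, "train_acc": tr, "test_acc": te, "val_acc": va}


class Adam:
    def __init__(self, net: Network, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(op.params[p]) for k, op, p in net.parameters()}
        self.v = {k: np.zeros_like(op.params[p]) for k, op, p in net.parameters()}

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, op, p in self.net.parameters():
            g = op.grads.get(p)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            op.params[p] = op.params[p] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.log(probs[np.arange(n), labels] + 1e-12).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


def _augment_batch(x: np.ndarray, rng: np.random.Generator,
                   zoom: bool, flip: bool, shear: bool) -> np.ndarray:
    out = np.empty_like(x)
    h, w = x.shape[1:3]
    for i, img in enumerate(x):
        a = img
        if flip:
            if rng.random() < 0.5:
                a = a[:, ::-1]
            if rng.random() < 0.5:
                a = a[::-1]
        mat = np.eye(2)
        if zoom:
            z = rng.uniform(0.85, 1.15)
            mat = mat @ np.array([[1 / z, 0.0], [0.0, 1 / z]])
        if shear:
            s = rng.uniform(-0.15, 0.15)
            mat = mat @ np.array([[1.0, s], [0.0, 1.0]])
        center = np.array([h / 2, w / 2])
        offset = center - mat @ center
        for ch in range(a.shape[2]):
            out[i, :, :, ch] = ndimage.affine_transform(
                a[:, :, ch], mat, offset=offset, order=1, mode="nearest"
            )
    return np.clip(out, 0.0, 1.0)


def evaluate(net: Network, images: np.ndarray, labels: np.ndarray,
             batch: int = 64) -> float:
    """Classification accuracy in percent."""
    if len(images) == 0:
        raise ValueError("cannot evaluate on an empty set")
    correct = 0
    for i in range(0, len(images), batch):
        pred = net.predict(images[i : i + batch])
        correct += int((pred == labels[i : i + batch]).sum())
    return 100.0 * correct / len(images)


def train(net: Network, dataset, config: TrainConfig) -> TrainResult:
    """Train ``net`` on a :class:`~ssimcut.synthetic.SyntheticDataset`-like
    object exposing ``images``, ``labels`` and ``split`` index arrays.

    Accuracy on the train/test/validation splits is recorded after every
    epoch; ``best_epoch`` is the epoch of maximum test accuracy.
    """
    tr_idx = np.asarray(dataset.split["train"])
    te_idx = np.asarray(dataset.split["test"])
    va_idx = np.asarray(dataset.split["validation"])
    if min(len(tr_idx), len(te_idx), len(va_idx)) == 0:
        raise ValueError("dataset has an empty split")
    n_classes = int(dataset.labels.max()) + 1
    head = net.nodes[-1].op
    if getattr(head, "d_out", n_classes) != n_classes:
        raise ValueError(
            f"model has {head.d_out} outputs but dataset has {n_classes} classes"
        )

    rng = np.random.default_rng(config.seed)
    opt = Adam(net, lr=config.learning_rate)
    x_tr = dataset.images[tr_idx].astype(np.float32)
    y_tr = dataset.labels[tr_idx]

    tr_hist, te_hist, va_hist = [], [], []
    for _ in range(config.epochs):
        order = rng.permutation(len(tr_idx))
        for i in range(0, len(order), config.minibatch):
            sel = order[i : i + config.minibatch]
            _train_step(net, opt, x_tr[sel], y_tr[sel])
        if config.augment:
            sel = rng.choice(len(tr_idx), size=min(config.minibatch, len(tr_idx)),
                             replace=False)
            xa = _augment_batch(x_tr[sel], rng, config.zoom, config.flip, config.shear)
            _train_step(net, opt, xa, y_tr[sel])
        tr_hist.append(evaluate(net, dataset.images[tr_idx], y_tr))
        te_hist.append(evaluate(net, dataset.images[te_idx], dataset.labels[te_idx]))
        va_hist.append(evaluate(net, dataset.images[va_idx], dataset.labels[va_idx]))

    best = int(np.argmax(te_hist)) + 1
    return TrainResult(tr_hist, te_hist, va_hist, best)


def _train_step(net: Network, opt: Adam, x: np.ndarray, y: np.ndarray) -> None:
    outs = net.forward(x, train=True)
    _, dlogits = softmax_cross_entropy(outs[-1], y)
    net.backward(outs, len(net.nodes), dlogits, guided=False)
    opt.step()
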