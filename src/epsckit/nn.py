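"""Minimal dense-network training core.

Implements exactly what the autoclassifier needs and nothing more: fully
connected layers with relu / softmax / linear activations, an L1 weight
penalty, inverted dropout, the Adam optimizer, Huber and softmax
cross-entropy losses, and a reduce-on-plateau learning-rate schedule.
Everything is float32 numpy and seeded.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Dropout", "Network", "fit_network"]

_F = np.float32


class Dense:
    """Fully connected layer with optional activation and L1 weight penalty."""

    def __init__(self, n_in: int, n_out: int, activation: str = "relu",
                 l1: float = 0.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        if activation not in ("relu", "linear", "softmax"):
            raise ValueError(f"unknown activation {activation!r}")
        # He init for relu, Glorot otherwise
        scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
        self.W = rng.standard_normal((n_in, n_out)).astype(_F) * _F(scale)
        self.b = np.zeros(n_out, dtype=_F)
        self.activation = activation
        self.l1 = l1
        self._x = None
        self._a = None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "relu":
            a = np.maximum(z, 0)
        elif self.activation == "softmax":
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            a = e / e.sum(axis=1, keepdims=True)
        else:
            a = z
        if train:
            self._x, self._a = x, a
        return a

    def backward(self, grad_a: np.ndarray) -> np.ndarray:
        a = self._a
        if self.activation == "relu":
            grad_z = grad_a * (a > 0)
        elif self.activation == "softmax":
            # full softmax Jacobian, row-wise: a * (g - <g, a>)
            dot = (grad_a * a).sum(axis=1, keepdims=True)
            grad_z = a * (grad_a - dot)
        else:
            grad_z = grad_a
        self.gW = self._x.T @ grad_z
        if self.l1 > 0:
            self.gW += _F(self.l1) * np.sign(self.W)
        self.gb = grad_z.sum(axis=0)
        return grad_z @ self.W.T

    def penalty(self) -> float:
        return float(self.l1 * np.abs(self.W).sum()) if self.l1 > 0 else 0.0


class Dropout:
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate <= 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_F) / _F(keep)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict(self, x: np.ndarray, batch: int = 8192) -> np.ndarray:
        x = np.asarray(x, dtype=_F)
        outs = [self.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
        return np.concatenate(outs, axis=0) if outs else np.empty((0,))

    def dense_layers(self) -> list[Dense]:
        return [l for l in self.layers if isinstance(l, Dense)]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self.dense_layers():
            out += [l.W.copy(), l.b.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        dense = self.dense_layers()
        if len(weights) != 2 * len(dense):
            raise ValueError("weight list does not match network layout")
        for i, l in enumerate(dense):
            l.W = np.asarray(weights[2 * i], dtype=_F)
            l.b = np.asarray(weights[2 * i + 1], dtype=_F)


class _Adam:
    def __init__(self, net: Network, beta1=0.9, beta2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state = {}
        for i, l in enumerate(net.dense_layers()):
            self.state[i] = [np.zeros_like(l.W), np.zeros_like(l.W),
                             np.zeros_like(l.b), np.zeros_like(l.b)]

    def step(self, net: Network, lr: float) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, l in enumerate(net.dense_layers()):
            mW, vW, mb, vb = self.state[i]
            for p, g, m, v in ((l.W, l.gW, mW, vW), (l.b, l.gb, mb, vb)):
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _huber(pred: np.ndarray, target: np.ndarray, delta: float = 1.0):
    err = pred - target
    abs_err = np.abs(err)
    quad = np.minimum(abs_err, delta)
    loss = float(np.mean(0.5 * quad**2 + delta * (abs_err - quad)))
    grad = np.clip(err, -delta, delta) / _F(err.size)
    return loss, grad.astype(_F)


def _softmax_xent(logits: np.ndarray, onehot: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.sum(onehot * np.log(p + 1e-12), axis=1)))
    grad = (p - onehot) / _F(n)
    return loss, grad.astype(_F)


_LOSSES = {"huber": _huber, "softmax_cross_entropy": _softmax_xent}


def _eval_loss(net: Network, X, Y, loss_fn, batch: int = 8192) -> float:
    total, n = 0.0, 0
    for i in range(0, len(X), batch):
        pred = net.forward(X[i : i + batch])
        l, _ = loss_fn(pred, Y[i : i + batch])
        total += l * (len(X[i : i + batch]))
        n += len(X[i : i + batch])
    return total / max(n, 1)


def fit_network(
    net: Network,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    loss: str,
    epochs: int = 100,
    batch_size: int = 32,
    lr: float = 1e-3,
    lr_factor: float = 0.2,
    lr_patience: int = 10,
    min_lr: float = 1e-6,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Mini-batch Adam training with a reduce-on-plateau LR schedule.

    Returns a history dict with per-epoch training loss, validation loss
    (when validation data is given) and the learning rate used.
    Raises on divergence (non-finite loss).
    """
    rng = rng or np.random.default_rng()
    loss_fn = _LOSSES[loss]
    X = np.asarray(X, dtype=_F)
    Y = np.asarray(Y, dtype=_F)
    if X_val is not None:
        X_val = np.asarray(X_val, dtype=_F)
        Y_val = np.asarray(Y_val, dtype=_F)
    opt = _Adam(net)
    history = {"loss": [], "val_loss": [], "lr": []}
    best = np.inf
    stall = 0
    for _epoch in range(epochs):
        order = rng.permutation(len(X))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(X), batch_size):
            idx = order[i : i + batch_size]
            pred = net.forward(X[idx], train=True)
            l, grad = loss_fn(pred, Y[idx])
            if not np.isfinite(l):
                raise FloatingPointError("training diverged: non-finite loss")
            net.backward(grad)
            opt.step(net, lr)
            epoch_loss += l * len(idx)
            seen += len(idx)
        history["loss"].append(epoch_loss / max(seen, 1))
        history["lr"].append(lr)
        monitored = history["loss"][-1]
        if X_val is not None and len(X_val):
            val = _eval_loss(net, X_val, Y_val, loss_fn)
            history["val_loss"].append(val)
            monitored = val
        if monitored < best - 1e-12:
            best = monitored
            stall = 0
        else:
            stall += 1
            if stall >= lr_patience:
                lr = max(lr * lr_factor, min_lr)
                stall = 0
    return history
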