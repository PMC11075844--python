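"""Compact convolutional image classifier with a scikit-learn API.

Three 3x3 convolution - ReLU - 2x2 max-pool blocks, a flattened dense
softmax readout, trained from scratch with Adam on minibatches. The
network is deliberately small (~9k parameters): bicoherence heatmaps are
low-entropy images whose class signal is a localized intensity difference,
so a few thousand parameters suffice and training stays cheap and exactly
reproducible on a single CPU. 224x224 inputs are average-pooled to 56x56
before the first convolution.

Implemented directly on NumPy (im2col convolutions, explicit backward
passes) so training is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["CompactCNNClassifier"]


def _im2col(x: np.ndarray) -> np.ndarray:
    """3x3 same-padding patch matrix: (N,H,W,C) -> (N,H,W,9C)."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    cols = np.empty((n, h, w, 9 * c), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[..., k * c : (k + 1) * c] = xp[:, di : di + h, dj : dj + w, :]
            k += 1
    return cols


def _col2im(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, h, w, c = shape
    dxp = np.zeros((n, h + 2, w + 2, c), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, di : di + h, dj : dj + w, :] += dcols[..., k * c : (k + 1) * c]
            k += 1
    return dxp[:, 1:-1, 1:-1, :]


def _max_pool_factor(x: np.ndarray, f: int) -> np.ndarray:
    n, h, w, c = x.shape
    h2, w2 = h // f, w // f
    x = x[:, : h2 * f, : w2 * f, :]
    return x.reshape(n, h2, f, w2, f, c).max(axis=(2, 4))


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        r = (
            x[:, : h2 * 2, : w2 * 2, :]
            .reshape(n, h2, 2, w2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h2, w2, c, 4)
        )
        self._idx = np.argmax(r, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        h2, w2 = h // 2, w // 2
        dr = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, : h2 * 2, : w2 * 2, :] = (
            dr.reshape(n, h2, w2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h2 * 2, w2 * 2, c)
        )
        return dx


class _ConvBlock:
    """3x3 conv (same padding) + ReLU + 2x2 max pool."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * c_in))  # He initialization
        self.w = rng.normal(0.0, scale, size=(9 * c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.pool = _MaxPool2()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _im2col(x)
        self._in_shape = x.shape
        z = self._cols @ self.w + self.b
        self._relu_mask = z > 0
        return self.pool.forward(np.where(self._relu_mask, z, 0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz = self.pool.backward(dout)
        dz = np.where(self._relu_mask, dz, 0.0)
        self.dw = np.tensordot(self._cols, dz, axes=([0, 1, 2], [0, 1, 2]))
        self.db = dz.sum(axis=(0, 1, 2))
        dcols = dz @ self.w.T
        return _col2im(dcols, self._in_shape)

    @property
    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _Adam:
    """Adam with decoupled weight decay and optional cosine LR decay."""

    def __init__(self, lr: float, weight_decay=0.0, total_steps=0,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.base_lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.total_steps = total_steps
        self.t = 0
        self.state: dict[tuple, tuple] = {}

    def step(self, layers):
        self.t += 1
        lr = self.base_lr
        if self.total_steps:
            frac = min(1.0, self.t / self.total_steps)
            lr = self.base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))
        for li, layer in enumerate(layers):
            for name, p, gname in layer.params:
                g = getattr(layer, gname)
                key = (li, name)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                if self.weight_decay and p.ndim > 1:  # decay weights, not biases
                    p -= (lr * self.weight_decay) * p
                p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.w = rng.normal(0.0, scale, size=(d_in, d_out)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    @property
    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class CompactCNNClassifier(ClassifierMixin, BaseEstimator):
    """Small convolutional network for fixed-size RGB images.

    Parameters
    ----------
    learning_rate : float
        Adam initial learning rate (default 0.001).
    batch_size : int
        Minibatch size (default 32).
    max_epochs : int
        Upper bound on training epochs (default 60).
    validation_frequency : int
        Validation evaluations per epoch when a validation set is supplied
        to :meth:`fit` (default 3). The parameters with the best validation
        accuracy are retained.
    patience : int
        Stop early after this many validation evaluations without
        improvement; 0 (default) disables early stopping — with small
        validation sets early accuracy plateaus are too noisy to stop on,
        so training runs all epochs and the best-on-validation parameters
        are restored at the end.
    channels : tuple of int
        Output channels of the three convolution blocks.
    weight_decay : float
        Decoupled L2 decay applied to weight matrices (not biases); the
        dense readout sees few training subjects, so mild shrinkage guards
        against memorizing subject-specific pixels.
    lr_decay : bool
        Cosine-anneal the learning rate to zero over the training budget.
    downsample : int
        Max-pooling factor applied to the input before the first
        convolution (224 -> 56 at the default 4). Max pooling preserves
        the localized intensity peaks that carry the phase-coupling signal
        in bicoherence heatmaps, which plain subsampling would dilute.
    seed : int
        Seed for weight initialization and minibatch shuffling; fixed seed
        plus fixed data reproduces training exactly.
    """

    def __init__(
        self,
        learning_rate: float = 0.001,
        batch_size: int = 32,
        max_epochs: int = 60,
        validation_frequency: int = 3,
        patience: int = 0,
        channels: tuple[int, int, int] = (8, 16, 32),
        downsample: int = 4,
        weight_decay: float = 5e-4,
        lr_decay: bool = True,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.validation_frequency = validation_frequency
        self.patience = patience
        self.channels = channels
        self.downsample = downsample
        self.weight_decay = weight_decay
        self.lr_decay = lr_decay
        self.seed = seed

    # ------------------------------------------------------------------ #

    def _prepare(self, X: np.ndarray, fit: bool = False) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"expected images of shape (n, H, W, 3), got {X.shape}")
        X = X.astype(np.float32)
        if X.max() > 1.5:  # uint8-scaled input
            X = X / 255.0
        if self.downsample > 1:
            X = _max_pool_factor(X, self.downsample).astype(np.float32)
        if fit:
            # center on the training mean image so the constant heatmap
            # background does not dominate early training
            self.input_mean_ = X.mean(axis=0, keepdims=True)
        return X - self.input_mean_

    def _forward(self, x: np.ndarray) -> np.ndarray:
        for blk in self._blocks:
            x = blk.forward(x)
        # flatten, not global pooling: the class signal in bicoherence
        # heatmaps is a localized intensity difference at fixed bifrequency
        # positions, which spatial averaging would wash out
        self._feat_shape = x.shape
        feat = x.reshape(x.shape[0], -1)
        logits = self._head.forward(feat)
        return logits

    def _backward(self, dlogits: np.ndarray) -> None:
        dfeat = self._head.backward(dlogits)
        dx = dfeat.reshape(self._feat_shape).astype(np.float32)
        for blk in reversed(self._blocks):
            dx = blk.backward(dx)

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def _snapshot(self):
        return [
            (blk.w.copy(), blk.b.copy()) for blk in self._blocks
        ] + [(self._head.w.copy(), self._head.b.copy())]

    def _restore(self, snap):
        for blk, (w, b) in zip(self._blocks, snap[:-1]):
            blk.w, blk.b = w.copy(), b.copy()
        self._head.w, self._head.b = snap[-1][0].copy(), snap[-1][1].copy()

    # ------------------------------------------------------------------ #

    def fit(self, X, y, X_val=None, y_val=None):
        """Train with Adam; if a validation set is given, keep the
        best-on-validation parameters and optionally stop early."""
        X = self._prepare(X, fit=True)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("training set contains a single class")
        n_classes = len(self.classes_)
        rng = np.random.default_rng(self.seed)

        c_in = X.shape[-1]
        h, w = X.shape[1], X.shape[2]
        self._blocks = []
        for c_out in self.channels:
            self._blocks.append(_ConvBlock(c_in, c_out, rng))
            c_in = c_out
            h, w = h // 2, w // 2
        self._head = _Dense(h * w * c_in, n_classes, rng)
        n = X.shape[0]
        n_batches = max(1, -(-n // self.batch_size))
        opt = _Adam(
            self.learning_rate,
            weight_decay=self.weight_decay,
            total_steps=self.max_epochs * n_batches if self.lr_decay else 0,
        )

        have_val = X_val is not None and y_val is not None
        if have_val:
            Xv = self._prepare(X_val)
            yv = np.asarray(y_val)
            yv_idx = np.searchsorted(self.classes_, yv)
        val_every = max(1, n_batches // max(1, self.validation_frequency))

        best_acc, best_loss, best_snap, stall = -1.0, np.inf, None, 0
        self.history_ = {"loss": [], "val_accuracy": [], "val_loss": []}
        stop = False
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for bi in range(n_batches):
                sel = order[bi * self.batch_size : (bi + 1) * self.batch_size]
                xb, yb = X[sel], y_idx[sel]
                logits = self._forward(xb)
                probs = self._softmax(logits)
                loss = -np.mean(
                    np.log(probs[np.arange(len(yb)), yb] + 1e-12)
                )
                self.history_["loss"].append(float(loss))
                dlogits = probs.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                dlogits /= len(yb)
                self._backward(dlogits.astype(np.float32))
                opt.step(self._blocks + [self._head])

                if have_val and (bi + 1) % val_every == 0:
                    vlogits = self._forward(Xv)
                    vprobs = self._softmax(vlogits)
                    vpred = np.argmax(vlogits, axis=1)
                    # balanced accuracy: subject-level splits can leave the
                    # small validation set class-imbalanced, where plain
                    # accuracy would reward single-class collapse
                    per_class = [
                        float(np.mean(vpred[yv_idx == c] == c))
                        for c in range(n_classes)
                        if np.any(yv_idx == c)
                    ]
                    acc = float(np.mean(per_class))
                    vloss = -float(
                        np.mean(np.log(vprobs[np.arange(len(yv_idx)), yv_idx] + 1e-12))
                    )
                    self.history_["val_accuracy"].append(acc)
                    self.history_["val_loss"].append(vloss)
                    if acc > best_acc or (acc == best_acc and vloss < best_loss):
                        best_acc, best_loss = acc, vloss
                        best_snap, stall = self._snapshot(), 0
                    else:
                        stall += 1
                        if self.patience and stall >= self.patience:
                            stop = True
                            break
            if stop:
                break
        if have_val and best_snap is not None:
            self._restore(best_snap)
            self.best_val_accuracy_ = best_acc
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "classes_")
        X = self._prepare(X)
        out = []
        for i in range(0, X.shape[0], 256):
            out.append(self._softmax(self._forward(X[i : i + 256])))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
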