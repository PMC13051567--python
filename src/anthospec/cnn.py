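"""A small one-dimensional convolutional network for index-vector inputs.

Architecture (fixed, sized for a few-hundred-sample problem with ~40
features): conv(16 filters, kernel 3, same padding) -> ReLU -> conv(32,
kernel 3, same padding) -> ReLU -> global average pooling -> dense(32)
-> ReLU -> dense(1).  Trained with mean-squared-error loss and Adam on
standardised inputs/targets, with early stopping on an inner 20 % split
(patience 50, best weights restored).  All randomness (initialisation,
batching, the inner split) flows from one seed, so training is
bit-reproducible.

The implementation is plain numpy — forward and backward passes are a
few einsums — which keeps the package dependency-light and the training
loop fully deterministic.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["CNN1DRegressor"]

log = logging.getLogger(__name__)


def _conv_forward(x, W, b):
    """x: (B, C, L); W: (O, C, K) with same padding; returns (B, O, L)
    and the patch tensor used by backward."""
    K = W.shape[2]
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    L = x.shape[2]
    # patches[b, c, k, l] = xp[b, c, l + k]
    patches = np.stack([xp[:, :, k:k + L] for k in range(K)], axis=2)
    out = np.einsum("ock,bckl->bol", W, patches) + b[None, :, None]
    return out, patches


def _conv_backward(dout, patches, W, x_shape):
    """Gradients of a same-padded 1-D convolution."""
    K = W.shape[2]
    pad = K // 2
    B, C, L = x_shape
    dW = np.einsum("bol,bckl->ock", dout, patches)
    db = dout.sum(axis=(0, 2))
    dpatch = np.einsum("bol,ock->bckl", dout, W)
    dxp = np.zeros((B, C, L + 2 * pad))
    for k in range(K):
        dxp[:, :, k:k + L] += dpatch[:, :, k, :]
    return dxp[:, :, pad:pad + L], dW, db


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class CNN1DRegressor(BaseEstimator, RegressorMixin):
    """1-D CNN regressor with Adam training and early stopping."""

    def __init__(self, conv_filters=(16, 32), kernel_size: int = 3,
                 dense_units: int = 32, learning_rate: float = 1e-3,
                 batch_size: int = 16, max_epochs: int = 500,
                 patience: int = 50, val_fraction: float = 0.2,
                 seed: int = 0):
        self.conv_filters = conv_filters
        self.kernel_size = kernel_size
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # -- internals ----------------------------------------------------------

    def _init_params(self, rng, n_features):
        f1, f2 = self.conv_filters
        k = self.kernel_size
        he = lambda fan_in, *shape: (np.sqrt(2.0 / fan_in)
                                     * rng.standard_normal(shape))
        self._params = [
            he(k, f1, 1, k), np.zeros(f1),              # conv1
            he(f1 * k, f2, f1, k), np.zeros(f2),        # conv2
            he(f2, self.dense_units, f2), np.zeros(self.dense_units),
            he(self.dense_units, 1, self.dense_units), np.zeros(1),
        ]

    def _forward(self, x, cache=False):
        W1, b1, W2, b2, Wd, bd, Wo, bo = self._params
        z1, p1 = _conv_forward(x, W1, b1)
        a1 = np.maximum(z1, 0.0)
        z2, p2 = _conv_forward(a1, W2, b2)
        a2 = np.maximum(z2, 0.0)
        g = a2.mean(axis=2)                             # GAP: (B, f2)
        zd = g @ Wd.T + bd
        ad = np.maximum(zd, 0.0)
        out = (ad @ Wo.T + bo).ravel()
        if cache:
            self._cache = (x, z1, p1, a1, z2, p2, a2, g, zd, ad)
        return out

    def _backward(self, dout):
        W1, b1, W2, b2, Wd, bd, Wo, bo = self._params
        x, z1, p1, a1, z2, p2, a2, g, zd, ad = self._cache
        dWo = dout[:, None].T @ ad
        dbo = np.array([dout.sum()])
        dad = dout[:, None] @ Wo
        dzd = dad * (zd > 0)
        dWd = dzd.T @ g
        dbd = dzd.sum(axis=0)
        dg = dzd @ Wd
        L = a2.shape[2]
        da2 = np.repeat(dg[:, :, None] / L, L, axis=2)
        dz2 = da2 * (z2 > 0)
        da1, dW2, db2 = _conv_backward(dz2, p2, W2, a1.shape)
        dz1 = da1 * (z1 > 0)
        _, dW1, db1 = _conv_backward(dz1, p1, W1, x.shape)
        return [dW1, db1, dW2, db2, dWd, dbd, dWo, dbo]

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if p < self.kernel_size:
            raise ValueError("need at least kernel_size features")
        rng = np.random.default_rng(self.seed)
        self.x_mean_ = X.mean(axis=0)
        sx = X.std(axis=0)
        self.x_std_ = np.where(sx > 0, sx, 1.0)
        self.y_mean_ = y.mean()
        sy = y.std()
        self.y_std_ = sy if sy > 0 else 1.0
        Xs = ((X - self.x_mean_) / self.x_std_)[:, None, :]   # (n, 1, p)
        ys = (y - self.y_mean_) / self.y_std_

        n_val = max(1, int(round(self.val_fraction * n))) if n >= 5 else 0
        perm = rng.permutation(n)
        val, train = perm[:n_val], perm[n_val:]
        if train.size == 0:
            train, val = perm, np.array([], dtype=int)

        self._init_params(rng, p)
        opt = _Adam(self._params, lr=self.learning_rate)
        best = (np.inf, None, -1)
        history = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(train)
            for start in range(0, order.size, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = self._forward(Xs[idx], cache=True)
                err = pred - ys[idx]
                loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(lr={self.learning_rate}, batch={idx.size})")
                grads = self._backward(2.0 * err / idx.size)
                opt.step(self._params, grads)
            monitor = val if val.size else train
            val_mse = float(np.mean(
                (self._forward(Xs[monitor]) - ys[monitor]) ** 2))
            history.append(val_mse)
            if val_mse < best[0]:
                best = (val_mse, [w.copy() for w in self._params], epoch)
            elif epoch - best[2] >= self.patience:
                break
        if best[1] is not None:
            self._params = best[1]
        self.loss_history_ = np.asarray(history)
        self.n_epochs_ = len(history)
        self.best_params_ = {"epochs_trained": self.n_epochs_,
                             "best_epoch": best[2] + 1}
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Xs = ((X - self.x_mean_) / self.x_std_)[:, None, :]
        return self._forward(Xs) * self.y_std_ + self.y_mean_

    def weights_digest(self) -> str:
        """Hex digest of all weights; equal digests mean identical nets."""
        import hashlib
        h = hashlib.sha256()
        for w in self._params:
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()
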