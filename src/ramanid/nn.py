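"""Compact NumPy neural networks for spectrum classification.

Two small deep classifiers over the wavenumber axis, implemented directly in
NumPy (forward pass, manual backpropagation, Adam):

* :class:`CNN1D` — two 1-D convolution blocks (conv → ReLU → pooling) over
  the downsampled spectrum, global average pooling, dense softmax head.
  Convolutions see local band shapes regardless of their absolute position.
* :class:`LSTMNet` — the spectrum is cut into a sequence of contiguous
  wavenumber chunks and fed to a single LSTM layer; the final hidden state
  goes through a dense softmax head.  The recurrence reads the fingerprint
  region left to right like a sequence.

Both are deterministic given their seed, train for a fixed small number of
epochs (no early stopping) and are sized to train in seconds on one CPU.
Inputs are standardized per feature using training-set statistics.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNN1D", "LSTMNet"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _NumpyNet:
    """Shared fit loop: standardization, minibatch Adam, softmax CE."""

    def __init__(self, epochs: int, batch_size: int, lr: float, seed: int,
                 aug_noise: float = 0.1):
        self.epochs, self.batch_size, self.lr, self.seed = epochs, batch_size, lr, seed
        self.aug_noise = aug_noise
        self.params: dict[str, np.ndarray] = {}
        self._mu: np.ndarray | None = None
        self._sd: float = 1.0

    # subclasses: _init_params(p, n_classes, rng), _forward(X) -> (logits, cache),
    # _backward(cache, dlogits) -> grads
    def fit(self, X: np.ndarray, y: np.ndarray, n_classes: int) -> "_NumpyNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed)
        # centre per feature but scale globally: flat spectral regions carry
        # almost pure noise, and per-feature scaling would amplify them
        self._mu = X.mean(axis=0)
        self._sd = float(X.std()) or 1.0
        Xs = (X - self._mu) / self._sd
        self.n_classes = n_classes
        self._init_params(Xs.shape[1], n_classes, rng)
        opt = _Adam(self.params, self.lr)
        n = Xs.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                batch = Xs[idx]
                if self.aug_noise > 0:  # jitter augmentation against overfit
                    batch = batch + rng.normal(0.0, self.aug_noise, batch.shape)
                logits, cache = self._forward(batch)
                probs = _softmax(logits)
                dlogits = probs.copy()
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits /= len(idx)
                opt.step(self._backward(cache, dlogits))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        logits, _ = self._forward(Xs)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def _conv_scatter(dx: np.ndarray, idx: np.ndarray, dcols: np.ndarray) -> None:
    # accumulate window-column gradients back onto the input length axis
    B = dx.shape[0]
    np.add.at(dx, (np.arange(B)[:, None, None], idx[None, :, :]), dcols)


class CNN1D(_NumpyNet):
    """Two-block 1-D convolutional classifier over the spectrum.

    Architecture: mean-pool downsample (factor ``downsample``) → conv(k1,
    f1 filters) → ReLU → max-pool(p1) → conv(k2, f2 filters) → ReLU →
    flatten → dense softmax.  The flatten head keeps band position, which
    carries the signal when all species share the same peak positions and
    differ only in their amplitude pattern.
    """

    def __init__(self, downsample: int = 4, f1: int = 8, k1: int = 9,
                 p1: int = 4, f2: int = 16, k2: int = 5,
                 epochs: int = 30, batch_size: int = 32, lr: float = 3e-3,
                 seed: int = 0, aug_noise: float = 0.1):
        super().__init__(epochs, batch_size, lr, seed, aug_noise)
        self.downsample, self.f1, self.k1, self.p1 = downsample, f1, k1, p1
        self.f2, self.k2 = f2, k2

    def _pool_input(self, X: np.ndarray) -> np.ndarray:
        d = self.downsample
        if d <= 1:
            return X
        L = (X.shape[1] // d) * d
        return X[:, :L].reshape(X.shape[0], -1, d).mean(axis=2)

    def fit(self, X, y, n_classes):
        return super().fit(self._pool_input(np.asarray(X, dtype=float)), y, n_classes)

    def predict_proba(self, X):
        return super().predict_proba(self._pool_input(np.asarray(X, dtype=float)))

    def _init_params(self, p: int, n_classes: int, rng: np.random.Generator) -> None:
        k1, f1, k2, f2 = self.k1, self.f1, self.k2, self.f2
        L1 = p - k1 + 1
        Lpool = (L1 // self.p1)
        L2 = Lpool - k2 + 1
        if L2 < 1:
            raise ValueError(f"input of {p} points too short for this architecture")
        he = lambda fan, shape: rng.normal(0, np.sqrt(2.0 / fan), shape)
        self.params = {
            "W1": he(k1, (k1, f1)), "b1": np.zeros(f1),
            "W2": he(k2 * f1, (k2 * f1, f2)), "b2": np.zeros(f2),
            "W3": he(L2 * f2, (L2 * f2, n_classes)), "b3": np.zeros(n_classes),
        }

    def _forward(self, X: np.ndarray):
        P = self.params
        B, L = X.shape
        win1 = sliding_window_view(X, self.k1, axis=1)          # (B, L1, k1)
        z1 = win1 @ P["W1"] + P["b1"]                           # (B, L1, f1)
        a1 = np.maximum(z1, 0.0)
        L1 = a1.shape[1]
        Lp = (L1 // self.p1) * self.p1
        blocks = a1[:, :Lp].reshape(B, Lp // self.p1, self.p1, self.f1)
        amax = blocks.argmax(axis=2)                            # (B, Lp/p1, f1)
        pooled = np.take_along_axis(blocks, amax[:, :, None, :], axis=2)[:, :, 0, :]
        win2 = sliding_window_view(pooled, self.k2, axis=1)     # (B, L2, f1, k2)
        w2flat = win2.transpose(0, 1, 3, 2).reshape(B, win2.shape[1], -1)
        z2 = w2flat @ P["W2"] + P["b2"]                         # (B, L2, f2)
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(B, -1)                                # (B, L2*f2)
        logits = flat @ P["W3"] + P["b3"]
        cache = (X, win1, z1, a1, Lp, blocks.shape, amax, pooled, w2flat, z2, a2, flat)
        return logits, cache

    def _backward(self, cache, dlogits):
        P = self.params
        (X, win1, z1, a1, Lp, bshape, amax, pooled, w2flat, z2, a2, flat) = cache
        B, L = X.shape
        grads = {
            "W3": flat.T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        L2 = a2.shape[1]
        da2 = (dlogits @ P["W3"].T).reshape(B, L2, self.f2)
        dz2 = da2 * (z2 > 0)
        grads["W2"] = np.einsum("blk,blf->kf", w2flat, dz2)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dw2flat = dz2 @ P["W2"].T                               # (B, L2, k2*f1)
        dwin2 = dw2flat.reshape(B, L2, self.k2, self.f1)        # (k2 before f1)
        dpooled = np.zeros_like(pooled)
        idx2 = np.arange(L2)[:, None] + np.arange(self.k2)[None, :]
        # scatter over the pooled-length axis, one channel block at a time
        np.add.at(dpooled,
                  (np.arange(B)[:, None, None, None],
                   idx2[None, :, :, None],
                   np.arange(self.f1)[None, None, None, :]),
                  dwin2)
        # max-pool backward: route gradient to the argmax within each block
        dblocks = np.zeros(bshape)
        np.put_along_axis(dblocks, amax[:, :, None, :], dpooled[:, :, None, :], axis=2)
        da1 = np.zeros_like(a1)
        da1[:, :Lp] = dblocks.reshape(B, Lp, self.f1)
        dz1 = da1 * (z1 > 0)
        grads["W1"] = np.einsum("blk,blf->kf", win1, dz1)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads


class LSTMNet(_NumpyNet):
    """Single-layer LSTM over the spectrum read as a chunk sequence.

    The p-point spectrum is reshaped into ``n_steps`` contiguous chunks
    (trailing remainder dropped); each chunk is one timestep input.  The
    final hidden state feeds a dense softmax head.
    """

    def __init__(self, n_steps: int = 30, hidden: int = 64,
                 epochs: int = 30, batch_size: int = 32, lr: float = 3e-3,
                 seed: int = 0, aug_noise: float = 0.1):
        super().__init__(epochs, batch_size, lr, seed, aug_noise)
        self.n_steps, self.hidden = n_steps, hidden

    def _init_params(self, p: int, n_classes: int, rng: np.random.Generator) -> None:
        self.chunk = p // self.n_steps
        if self.chunk < 1:
            raise ValueError(f"spectrum of {p} points too short for "
                             f"{self.n_steps} sequence steps")
        D, H = self.chunk, self.hidden
        sc = lambda fan, shape: rng.normal(0, np.sqrt(1.0 / fan), shape)
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias
        self.params = {
            "Wx": sc(D, (D, 4 * H)), "Wh": sc(H, (H, 4 * H)), "b": b,
            "Wo": sc(H, (H, n_classes)), "bo": np.zeros(n_classes),
        }

    def _sequence(self, X: np.ndarray) -> np.ndarray:
        T, D = self.n_steps, self.chunk
        return X[:, :T * D].reshape(X.shape[0], T, D)

    def _forward(self, X: np.ndarray):
        P = self.params
        seq = self._sequence(X)
        B, T, D = seq.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        steps = []
        for t in range(T):
            a = seq[:, t] @ P["Wx"] + h @ P["Wh"] + P["b"]
            i, f, o = (_sigmoid(a[:, :H]), _sigmoid(a[:, H:2 * H]),
                       _sigmoid(a[:, 2 * H:3 * H]))
            g = np.tanh(a[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            steps.append((i, f, o, g, c_prev, h_prev, c))
        logits = h @ P["Wo"] + P["bo"]
        return logits, (seq, steps, h)

    def _backward(self, cache, dlogits):
        P = self.params
        seq, steps, hT = cache
        B, T, D = seq.shape
        H = self.hidden
        grads = {k: np.zeros_like(v) for k, v in P.items()}
        grads["Wo"] = hT.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ P["Wo"].T
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, o, g, c_prev, h_prev, c = steps[t]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 do * o * (1 - o), dg * (1 - g ** 2)], axis=1)
            grads["Wx"] += seq[:, t].T @ da
            grads["Wh"] += h_prev.T @ da
            grads["b"] += da.sum(axis=0)
            dh = da @ P["Wh"].T
            dc = dc * f
        return grads
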