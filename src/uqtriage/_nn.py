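"""Small dropout networks in plain numpy.

The deep-learning branch of the fusion model only needs to (a) emit class
probabilities, (b) keep dropout active at inference for Monte Carlo sampling,
and (c) expose last-convolutional-layer feature maps and their gradients for
class-activation mapping.  At desk scale that is served by two hand-sized
architectures trained with Adam on the cross-entropy loss:

* :class:`DropoutMLP` — dense net for tabular radiomic features;
* :class:`TinyConvNet3D` — one 3x3x3 "same" convolution, ReLU, dropout,
  global average pooling, and a linear softmax head, for toy volumes.

Both are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DropoutMLP", "TinyConvNet3D"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _one_hot(y: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(y), n))
    out[np.arange(len(y)), y] = 1.0
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class DropoutMLP:
    """Two-hidden-layer softmax classifier with inverted dropout.

    Parameters
    ----------
    n_features, n_classes
        Input / output dimensions.
    hidden
        Hidden layer widths.
    dropout
        Drop probability applied after each hidden activation, both during
        training and (on request) at inference — the Monte Carlo dropout
        regime.  Must lie in [0, 1).
    seed
        Controls weight init, training dropout masks, and shuffling.
    """

    def __init__(self, n_features: int, n_classes: int = 2,
                 hidden: tuple[int, ...] = (32, 16), dropout: float = 0.3,
                 seed: int = 0):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.dropout = float(dropout)
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        dims = (n_features, *hidden, n_classes)
        self.W = [rng.standard_normal((a, b)) * np.sqrt(2.0 / a)
                  for a, b in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(b) for b in dims[1:]]
        self._train_rng = rng
        self._mean = np.zeros(n_features)
        self._std = np.ones(n_features)

    # -- forward ----------------------------------------------------------
    def _forward(self, X: np.ndarray, rng: np.random.Generator | None,
                 ) -> tuple[np.ndarray, list]:
        X = (X - self._mean) / self._std
        caches = []
        h = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < len(self.W) - 1:
                a = np.maximum(z, 0.0)
                if rng is not None and self.dropout > 0:
                    mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                    a = a * mask
                else:
                    mask = None
                caches.append((h, z, a, mask))
                h = a
            else:
                caches.append((h, z, None, None))
        return _softmax(z), caches

    def predict_proba(self, X: np.ndarray, rng: np.random.Generator | None = None,
                      ) -> np.ndarray:
        """Class probabilities; pass an ``rng`` to sample a dropout mask."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._forward(X, rng)[0]

    # -- training ---------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 300,
            lr: float = 0.01) -> "DropoutMLP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self._mean = X.mean(axis=0)
        self._std = X.std(axis=0)
        self._std[self._std == 0] = 1.0
        Y = _one_hot(y, self.n_classes)
        opt = _Adam(self.W + self.b, lr)
        n = len(X)
        for _ in range(epochs):
            P, caches = self._forward(X, self._train_rng)
            dz = (P - Y) / n
            gW, gb = [], []
            for i in range(len(self.W) - 1, -1, -1):
                h_in = caches[i][0]
                gW.append(h_in.T @ dz)
                gb.append(dz.sum(axis=0))
                if i > 0:
                    da = dz @ self.W[i].T
                    _, z_prev, _, mask_prev = caches[i - 1]
                    if mask_prev is not None:
                        da = da * mask_prev
                    dz = da * (z_prev > 0)
            opt.step(list(reversed(gW)) + list(reversed(gb)))
        return self


def _im2col3d(X: np.ndarray, k: int = 3) -> np.ndarray:
    """(n, D, H, W) -> (n, D*H*W, k^3) patches with zero 'same' padding."""
    pad = k // 2
    Xp = np.pad(X, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(Xp, (k, k, k), axis=(1, 2, 3))
    n, D, H, W = X.shape
    return win.reshape(n, D * H * W, k ** 3)


class TinyConvNet3D:
    """Conv(3x3x3, same) -> ReLU -> dropout -> GAP -> linear softmax.

    The single convolutional layer doubles as "the last convolutional layer"
    for gradient-weighted class-activation mapping: with global average
    pooling and a linear head the gradient of the class score with respect
    to feature map ``k`` is spatially constant and equals ``w[k, class] / V``
    (V = voxel count), so the channel weights of the activation map are exact.
    """

    def __init__(self, channels: int = 4, kernel: int = 3, dropout: float = 0.3,
                 n_classes: int = 2, seed: int = 0):
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.dropout = float(dropout)
        self.channels = channels
        self.kernel = kernel
        self.n_classes = n_classes
        rng = np.random.default_rng(seed)
        self.Wc = rng.standard_normal((kernel ** 3, channels)) * np.sqrt(2.0 / kernel ** 3)
        self.bc = np.zeros(channels)
        self.Wd = rng.standard_normal((channels, n_classes)) * np.sqrt(2.0 / channels)
        self.bd = np.zeros(n_classes)
        self._train_rng = rng

    @property
    def has_conv(self) -> bool:
        return True

    def _conv(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cols = _im2col3d(X, self.kernel)          # (n, V, k^3)
        z = cols @ self.Wc + self.bc              # (n, V, C)
        return z, cols

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        z, cols = self._conv(X)
        a = np.maximum(z, 0.0)
        if rng is not None and self.dropout > 0:
            mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
            a = a * mask
        else:
            mask = None
        g = a.mean(axis=1)                        # GAP over voxels, (n, C)
        logits = g @ self.Wd + self.bd
        return _softmax(logits), (cols, z, a, mask, g)

    def predict_proba(self, X: np.ndarray, rng: np.random.Generator | None = None,
                      ) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[None]
        return self._forward(X, rng)[0]

    def _forward_cols(self, cols: np.ndarray, rng: np.random.Generator | None):
        z = cols @ self.Wc + self.bc
        a = np.maximum(z, 0.0)
        if rng is not None and self.dropout > 0:
            mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
            a = a * mask
        else:
            mask = None
        g = a.mean(axis=1)
        logits = g @ self.Wd + self.bd
        return _softmax(logits), (cols, z, a, mask, g)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 200,
            lr: float = 0.02) -> "TinyConvNet3D":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        Y = _one_hot(y, self.n_classes)
        opt = _Adam([self.Wc, self.bc, self.Wd, self.bd], lr)
        n, V = len(X), int(np.prod(X.shape[1:]))
        cached_cols = _im2col3d(X, self.kernel)   # input patches are static
        for _ in range(epochs):
            P, (cols, z, a, mask, g) = self._forward_cols(cached_cols, self._train_rng)
            dlogits = (P - Y) / n
            gWd = g.T @ dlogits
            gbd = dlogits.sum(axis=0)
            dg = dlogits @ self.Wd.T                     # (n, C)
            da = np.repeat(dg[:, None, :], V, axis=1) / V
            if mask is not None:
                da = da * mask
            dz = da * (z > 0)
            gWc = np.einsum("nvk,nvc->kc", cols, dz)
            gbc = dz.sum(axis=(0, 1))
            opt.step([gWc, gbc, gWd, gbd])
        return self

    def feature_maps(self, x: np.ndarray) -> np.ndarray:
        """Post-ReLU conv activations, shape (channels, D, H, W)."""
        x = np.asarray(x, dtype=float)[None]
        z, _ = self._conv(x)
        a = np.maximum(z, 0.0)[0]                 # (V, C)
        return a.T.reshape(self.channels, *x.shape[1:])

    def cam_channel_weights(self, target_class: int, volume_voxels: int) -> np.ndarray:
        """d(score_class)/d(A_k), spatially averaged — exact for GAP+linear."""
        return self.Wd[:, target_class] / volume_voxels
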