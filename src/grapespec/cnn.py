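"""A compact, fully deterministic 1-D convolutional network in NumPy.

The network maps a pre-treated spectrum (one channel, n_bands long) to a
single °Brix value: a stack of 1-D convolutional blocks (convolution,
optional batch normalization, ReLU, optional max pooling with window 2) acts
as feature extractor, followed by fully connected ReLU layers (with L2
penalty on their weights) and a single linear output neuron.

Training uses mean-squared-error loss with the Adam optimizer, a step-decay
schedule halving the learning rate every 60 epochs, at most 200 epochs, and
early stopping on validation loss with patience 40 (restoring the best
weights).  Inputs may be standardized per band (min-max to [-1, 1] or
standard score) and the target is internally standardized; all statistics are
computed on the training partition only.

Everything is seeded through ``numpy.random.Generator``, so a fit is
bit-reproducible given (data, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CnnConfig", "CnnModel", "DENSE_L2", "MAX_EPOCHS", "PATIENCE", "LR_DECAY_EPOCHS"]

DTYPE = np.float32     # training is done in single precision for speed

DENSE_L2 = 0.0004      # L2 penalty on fully-connected weights
MAX_EPOCHS = 200
PATIENCE = 40          # early-stopping patience (epochs), on validation loss
LR_DECAY_EPOCHS = 60   # halve the learning rate every this many epochs


@dataclass(frozen=True)
class CnnConfig:
    """One point of the CNN hyperparameter space.

    ``filters``/``dense_units`` have one entry per convolutional / fully
    connected layer respectively; ``standardization`` is one of
    {"none", "minmax", "standard"}."""

    standardization: str = "standard"
    filters: tuple[int, ...] = (16,)
    kernel_size: int = 5
    batch_norm: bool = False
    max_pool: bool = True
    dense_units: tuple[int, ...] = (32,)
    batch_size: int = 8
    learning_rate: float = 1e-3

    @property
    def n_conv(self) -> int:
        return len(self.filters)

    @property
    def n_dense(self) -> int:
        return len(self.dense_units)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    weight_decay: list[float]

    def __init__(self) -> None:
        self.params, self.grads, self.weight_decay = [], [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Conv1D(_Layer):
    """Valid 1-D convolution: (N, C, L) -> (N, F, L - K + 1).

    Implemented as im2col + matmul; the column matrix is cached for the
    weight-gradient pass."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = rng.normal(0.0, scale, (out_ch, in_ch, kernel)).astype(DTYPE)
        self.b = np.zeros(out_ch, dtype=DTYPE)
        self.kernel = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.weight_decay = [0.0, 0.0]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        k = self.kernel
        lo = length - k + 1
        self._in_len = length
        xw = sliding_window_view(x, k, axis=2)            # (N, C, L', K)
        self._xcol = np.ascontiguousarray(xw.transpose(0, 2, 1, 3)).reshape(n * lo, c * k)
        w2 = self.W.reshape(self.out_ch, c * k)
        out = self._xcol @ w2.T + self.b                  # (N*L', F)
        return out.reshape(n, lo, self.out_ch).transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, lo = dout.shape
        k, c = self.kernel, self.in_ch
        dflat = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(n * lo, f)
        self.grads[0][...] = (dflat.T @ self._xcol).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        dcol = (dflat @ self.W.reshape(f, c * k)).reshape(n, lo, c, k)
        dx = np.zeros((n, c, self._in_len), dtype=DTYPE)
        for j in range(k):  # col2im scatter-add, K <= 7
            dx[:, :, j:j + lo] += dcol[:, :, :, j].transpose(0, 2, 1)
        return dx


class _BatchNorm1D(_Layer):
    """Per-channel batch normalization over the (sample, position) axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.run_mean = np.zeros(channels, dtype=DTYPE)
        self.run_var = np.ones(channels, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.weight_decay = [0.0, 0.0]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        m = dout.shape[0] * dout.shape[2]
        self.grads[0][...] = (dout * self._xhat).sum(axis=(0, 2))
        self.grads[1][...] = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2), keepdims=True)
        ) / self._std[None, :, None]
        return dx


class _ReLU(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, DTYPE(0))
        if train:
            self._mask = out > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool2(_Layer):
    """Max pooling, window 2 and stride 2 (halving); odd tails are dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        self._in_len = length
        half = length // 2
        a = x[:, :, 0:2 * half:2]
        b = x[:, :, 1:2 * half:2]
        self._right = b > a  # tie goes to the left element
        return np.where(self._right, b, a)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, half = dout.shape
        dx = np.zeros((n, c, self._in_len), dtype=DTYPE)
        dx[:, :, 0:2 * half:2] = np.where(self._right, 0.0, dout)
        dx[:, :, 1:2 * half:2] = np.where(self._right, dout, 0.0)
        return dx


class _Flatten(_Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, l2: float = 0.0):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.weight_decay = [l2, 0.0]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class _Adam:
    """Adam over one flat parameter vector (layers hold views into it)."""

    def __init__(self, theta: np.ndarray, grad: np.ndarray, wd2: np.ndarray,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.theta, self.grad, self.wd2 = theta, grad, wd2
        self.beta1, self.beta2, self.eps = DTYPE(beta1), DTYPE(beta2), DTYPE(eps)
        self.t = 0
        self.m = np.zeros_like(theta)
        self.v = np.zeros_like(theta)
        self._has_wd = bool(np.any(wd2))

    def step(self, lr: float) -> None:
        self.t += 1
        b1c = DTYPE(1.0 - float(self.beta1) ** self.t)
        b2c = DTYPE(1.0 - float(self.beta2) ** self.t)
        g = self.grad
        if self._has_wd:
            g = g + self.wd2 * self.theta
        self.m += (DTYPE(1) - self.beta1) * (g - self.m)
        self.v += (DTYPE(1) - self.beta2) * (g * g - self.v)
        self.theta -= DTYPE(lr) * (self.m / b1c) / (np.sqrt(self.v / b2c) + self.eps)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class CnnModel:
    """Trainable 1-D CNN for spectral regression (single scalar output)."""

    def __init__(self, config: CnnConfig, n_features: int, seed: int = 0):
        self.config = config
        self.n_features = int(n_features)
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)
        self._build()
        self._x_stats: tuple[np.ndarray, np.ndarray] | None = None
        self._y_stats: tuple[float, float] = (0.0, 1.0)

    def _build(self) -> None:
        cfg = self.config
        layers: list[_Layer] = []
        in_ch, length = 1, self.n_features
        for f in cfg.filters:
            if length < cfg.kernel_size:
                raise ValueError(
                    f"feature length {length} shrank below kernel size {cfg.kernel_size}"
                )
            layers.append(_Conv1D(in_ch, f, cfg.kernel_size, self._rng))
            length = length - cfg.kernel_size + 1
            if cfg.batch_norm:
                layers.append(_BatchNorm1D(f))
            layers.append(_ReLU())
            if cfg.max_pool:
                layers.append(_MaxPool2())
                length = length // 2
            in_ch = f
        if length < 1:
            raise ValueError("feature length pooled away to zero; config infeasible")
        layers.append(_Flatten())
        n_in = in_ch * length
        for u in cfg.dense_units:
            layers.append(_Dense(n_in, u, self._rng, l2=DENSE_L2))
            layers.append(_ReLU())
            n_in = u
        layers.append(_Dense(n_in, 1, self._rng))
        self.layers = layers
        self._flatten_params()

    def _flatten_params(self) -> None:
        """Move every trainable array into one contiguous buffer; layers keep
        views, so a single vectorized Adam update covers the whole network."""
        total = sum(p.size for lay in self.layers for p in lay.params)
        theta = np.empty(total, dtype=DTYPE)
        grad = np.zeros(total, dtype=DTYPE)
        wd2 = np.zeros(total, dtype=DTYPE)
        off = 0
        for lay in self.layers:
            for i, p in enumerate(lay.params):
                sl = slice(off, off + p.size)
                theta[sl] = p.ravel()
                view = theta[sl].reshape(p.shape)
                gview = grad[sl].reshape(p.shape)
                wd2[sl] = 2.0 * lay.weight_decay[i]
                for attr, val in vars(lay).items():  # rebind named attrs (W, b, ...)
                    if val is p:
                        setattr(lay, attr, view)
                lay.params[i] = view
                lay.grads[i] = gview
                off += p.size
        self._theta, self._grad, self._wd2 = theta, grad, wd2

    # -- bookkeeping -------------------------------------------------------

    def param_count(self) -> int:
        """Number of trainable parameters (running BN statistics excluded)."""
        return int(sum(p.size for lay in self.layers for p in lay.params))

    def _state_arrays(self) -> list[np.ndarray]:
        arrays = [self._theta]
        for lay in self.layers:  # BN running statistics travel with the weights
            if isinstance(lay, _BatchNorm1D):
                arrays += [lay.run_mean, lay.run_var]
        return arrays

    def _snapshot(self) -> list[np.ndarray]:
        return [a.copy() for a in self._state_arrays()]

    def _restore(self, snap: list[np.ndarray]) -> None:
        for a, s in zip(self._state_arrays(), snap):
            a[...] = s

    # -- input/target standardization -------------------------------------

    def _fit_x_stats(self, X: np.ndarray) -> None:
        mode = self.config.standardization
        if mode == "none":
            self._x_stats = None
        elif mode == "minmax":
            lo, hi = X.min(axis=0), X.max(axis=0)
            span = np.where(hi > lo, hi - lo, 1.0)
            self._x_stats = (lo, span)
        elif mode == "standard":
            mu, sd = X.mean(axis=0), X.std(axis=0)
            self._x_stats = (mu, np.where(sd > 0, sd, 1.0))
        else:
            raise ValueError(f"unknown standardization {mode!r}")

    def _transform_x(self, X: np.ndarray) -> np.ndarray:
        mode = self.config.standardization
        if mode == "minmax":
            lo, span = self._x_stats
            X = 2.0 * (X - lo) / span - 1.0
        elif mode == "standard":
            mu, sd = self._x_stats
            X = (X - mu) / sd
        return np.ascontiguousarray(X[:, None, :], dtype=DTYPE)  # add channel axis

    def _forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x[:, 0]

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        max_epochs: int = MAX_EPOCHS,
        patience: int = PATIENCE,
        resume: bool = False,
    ) -> "CnnModel":
        """Train (or, with ``resume=True``, continue training on the same data
        up to a larger cumulative epoch budget — used by successive halving).

        ``max_epochs`` is the cumulative epoch budget; the learning-rate
        schedule, optimizer state and early-stopping bookkeeping carry over
        across resumed segments.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not resume:
            self._fit_x_stats(X)
            y_mu, y_sd = float(y.mean()), float(y.std())
            self._y_stats = (y_mu, y_sd if y_sd > 0 else 1.0)
            self._opt = _Adam(self._theta, self._grad, self._wd2)
            self._epoch = 0
            self._best_val = np.inf
            self._best_snap: list[np.ndarray] | None = None
            self._wait = 0
            self._stopped = False
            self.history: list[float] = []
        yt = ((y - self._y_stats[0]) / self._y_stats[1]).astype(DTYPE)

        Xt = self._transform_x(X)
        if X_val is not None:
            Xv = self._transform_x(np.asarray(X_val, dtype=float))
            yv = ((np.asarray(y_val, dtype=float) - self._y_stats[0]) / self._y_stats[1]).astype(DTYPE)

        n = Xt.shape[0]
        bs = min(self.config.batch_size, n)

        while self._epoch < max_epochs and not self._stopped:
            lr = self.config.learning_rate * 0.5 ** (self._epoch // LR_DECAY_EPOCHS)
            order = self._rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                pred = self._forward(Xt[idx], train=True)
                resid = pred - yt[idx]
                dout = (DTYPE(2.0 / idx.size) * resid)[:, None]
                x = dout
                for lay in reversed(self.layers):
                    x = lay.backward(x)
                self._opt.step(lr)
            self._epoch += 1
            if X_val is not None and len(yv):
                val = float(np.mean((self._forward(Xv, train=False) - yv) ** 2))
                self.history.append(val)
                if val < self._best_val - 1e-12:
                    self._best_val = val
                    self._best_snap = self._snapshot()
                    self._wait = 0
                else:
                    self._wait += 1
                    if self._wait >= patience:
                        self._stopped = True
        self.best_val_loss_ = self._best_val if self._best_val < np.inf else None
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict with the best weights seen on the validation set (or the
        final weights when no validation set was used)."""
        Xt = self._transform_x(np.asarray(X, dtype=float))
        if getattr(self, "_best_snap", None) is not None:
            current = self._snapshot()
            self._restore(self._best_snap)
            out = self._forward(Xt, train=False).astype(float)
            self._restore(current)
        else:
            out = self._forward(Xt, train=False).astype(float)
        return out * self._y_stats[1] + self._y_stats[0]
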