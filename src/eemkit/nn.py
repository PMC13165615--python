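"""Minimal feed-forward network engine (NumPy, CPU).

Implements exactly the building blocks the regression CNNs need: valid
1-D/2-D convolution, ReLU, max pooling, flatten, dense, inverted dropout,
He-normal initialization, an Adam optimizer and an MSE training loop with
early stopping, best-weight restoration and reduce-on-plateau learning-rate
scheduling.  Everything runs in float32; convolution uses an im2col +
matmul formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Sequential", "Conv1D", "Conv2D", "ReLU", "MaxPool1D", "MaxPool2D",
           "Flatten", "Dense", "Dropout", "Adam", "fit_regressor", "TrainHistory"]


class Layer:
    """Base layer: parameter-free unless it overrides ``params``."""

    name = "layer"

    def build(self, input_shape, rng):
        return self.output_shape(input_shape)

    def output_shape(self, input_shape):
        return input_shape

    @property
    def params(self):
        return []

    @property
    def grads(self):
        return []

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, dout, need_input_grad=True):
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (no-padding) 1-D convolution; input (N, L, C)."""

    def __init__(self, filters: int, kernel: int):
        self.filters, self.kernel = filters, kernel
        self.name = f"conv1d({filters}x{kernel})"

    def build(self, input_shape, rng):
        L, C = input_shape
        if L <= self.kernel:
            raise ValueError(f"input length {L} must exceed kernel {self.kernel}")
        fan_in = self.kernel * C
        self.W = (rng.standard_normal((self.kernel, C, self.filters))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(self.filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        return self.output_shape(input_shape)

    def output_shape(self, input_shape):
        L, C = input_shape
        return (L - self.kernel + 1, self.filters)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False, rng=None):
        N, L, C = x.shape
        cols = sliding_window_view(x, self.kernel, axis=1)  # (N, Lout, C, K)
        cols = np.ascontiguousarray(np.moveaxis(cols, 3, 2))  # (N, Lout, K, C)
        self._cols = cols.reshape(-1, self.kernel * C)
        self._in_shape = x.shape
        out = self._cols @ self.W.reshape(-1, self.filters) + self.b
        return out.reshape(N, L - self.kernel + 1, self.filters)

    def backward(self, dout, need_input_grad=True):
        N, Lout, F = dout.shape
        dflat = dout.reshape(-1, F)
        self.dW[...] = (self._cols.T @ dflat).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        if not need_input_grad:
            return None
        _, L, C = self._in_shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for k in range(self.kernel):
            dx[:, k:k + Lout, :] += dflat.reshape(N, Lout, F) @ self.W[k].T
        return dx


class Conv2D(Layer):
    """Valid 2-D convolution; input (N, H, W, C)."""

    def __init__(self, filters: int, kernel: tuple[int, int] = (3, 3)):
        self.filters = filters
        self.kh, self.kw = kernel
        self.name = f"conv2d({filters}x{self.kh}x{self.kw})"

    def build(self, input_shape, rng):
        H, W, C = input_shape
        if H < self.kh or W < self.kw:
            raise ValueError("input smaller than kernel")
        fan_in = self.kh * self.kw * C
        self.W = (rng.standard_normal((self.kh, self.kw, C, self.filters))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(self.filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        return self.output_shape(input_shape)

    def output_shape(self, input_shape):
        H, W, C = input_shape
        return (H - self.kh + 1, W - self.kw + 1, self.filters)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False, rng=None):
        # convolution as kh*kw shifted matmuls: avoids materializing the
        # full im2col tensor, which dominates runtime at 224 px inputs
        N, H, W, C = x.shape
        Hout, Wout = H - self.kh + 1, W - self.kw + 1
        self._x = x
        out = np.empty((N, Hout, Wout, self.filters), dtype=np.float32)
        out[...] = self.b
        for i in range(self.kh):
            for j in range(self.kw):
                out += x[:, i:i + Hout, j:j + Wout, :] @ self.W[i, j]
        return out

    def backward(self, dout, need_input_grad=True):
        N, Hout, Wout, F = dout.shape
        dflat = dout.reshape(-1, F)
        self.db[...] = dflat.sum(axis=0)
        x = self._x
        for i in range(self.kh):
            for j in range(self.kw):
                patch = x[:, i:i + Hout, j:j + Wout, :].reshape(-1, x.shape[3])
                self.dW[i, j] = patch.T @ dflat
        if not need_input_grad:
            return None
        dx = np.zeros(x.shape, dtype=np.float32)
        dr = dflat.reshape(N, Hout, Wout, F)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i:i + Hout, j:j + Wout, :] += dr @ self.W[i, j].T
        return dx


class ReLU(Layer):
    name = "relu"

    def forward(self, x, training=False, rng=None):
        out = np.maximum(x, 0.0, out=x)  # safe: upstream output is fresh
        self._out = out
        return out

    def backward(self, dout, need_input_grad=True):
        dout *= self._out > 0
        return dout


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2):
        self.pool = pool
        self.name = f"maxpool1d({pool})"

    def output_shape(self, input_shape):
        L, C = input_shape
        return (L // self.pool, C)

    def forward(self, x, training=False, rng=None):
        N, L, C = x.shape
        Lc = (L // self.pool) * self.pool
        xr = x[:, :Lc].reshape(N, L // self.pool, self.pool, C)
        self._arg = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout, need_input_grad=True):
        N, Lp, C = dout.shape
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dxr = dx[:, : Lp * self.pool].reshape(N, Lp, self.pool, C)
        n, l, c = np.ogrid[:N, :Lp, :C]
        dxr[n, l, self._arg, c] = dout
        return dx


class MaxPool2D(Layer):
    def __init__(self, pool: tuple[int, int] = (2, 2)):
        self.ph, self.pw = pool
        self.name = f"maxpool2d({self.ph}x{self.pw})"

    def output_shape(self, input_shape):
        H, W, C = input_shape
        return (H // self.ph, W // self.pw, C)

    def forward(self, x, training=False, rng=None):
        N, H, W, C = x.shape
        Hp, Wp = H // self.ph, W // self.pw
        out = None
        for i in range(self.ph):
            for j in range(self.pw):
                s = x[:, i : Hp * self.ph : self.ph, j : Wp * self.pw : self.pw, :]
                out = s.copy() if out is None else np.maximum(out, s, out=out)
        self._x = x
        self._out = out
        return out

    def backward(self, dout, need_input_grad=True):
        # route gradient to the first window element equal to the max
        # (exact float ties are rare; duplicates would split negligibly)
        N, Hp, Wp, C = dout.shape
        x = self._x
        dx = np.zeros(x.shape, dtype=np.float32)
        taken = np.zeros(dout.shape, dtype=bool)
        for i in range(self.ph):
            for j in range(self.pw):
                s = x[:, i : Hp * self.ph : self.ph, j : Wp * self.pw : self.pw, :]
                hit = (s == self._out) & ~taken
                taken |= hit
                dx[:, i : Hp * self.ph : self.ph, j : Wp * self.pw : self.pw, :] = (
                    dout * hit
                )
        return dx


class Flatten(Layer):
    name = "flatten"

    def output_shape(self, input_shape):
        return (int(np.prod(input_shape)),)

    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout, need_input_grad=True):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, units: int):
        self.units = units
        self.name = f"dense({units})"

    def build(self, input_shape, rng):
        (fan_in,) = input_shape
        self.W = (rng.standard_normal((fan_in, self.units))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(self.units, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        return (self.units,)

    def output_shape(self, input_shape):
        return (self.units,)

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout, need_input_grad=True):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        if not need_input_grad:
            return None
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.name = f"dropout({rate})"

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout, need_input_grad=True):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    """Ordered layer stack with a fixed input shape (excluding batch)."""

    def __init__(self, layers: list[Layer], input_shape: tuple[int, ...], seed: int = 0):
        self.layers = layers
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape
        self._dropout_rng = np.random.default_rng(seed + 1)

    @property
    def layer_names(self) -> list[str]:
        return [layer.name for layer in self.layers]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def layer_param_counts(self) -> dict[str, int]:
        return {layer.name: int(sum(p.size for p in layer.params)) for layer in self.layers}

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input {self.input_shape}"
            )
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=self._dropout_rng)
        return x

    def backward(self, dout):
        for i in range(len(self.layers) - 1, -1, -1):
            dout = self.layers[i].backward(dout, need_input_grad=(i > 0))

    def predict(self, x, batch_size: int = 32) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [self.forward(x[i:i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(outs).ravel()

    def get_weights(self):
        return [p.copy() for p in self.params]

    def set_weights(self, weights):
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self._buf = [np.empty_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v, buf in zip(self.params, grads, self.m, self.v, self._buf):
            m *= self.beta1
            np.multiply(g, 1.0 - self.beta1, out=buf)
            m += buf
            v *= self.beta2
            np.multiply(g, g, out=buf)
            buf *= 1.0 - self.beta2
            v += buf
            np.multiply(v, 1.0 / b2t, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= self.lr / b1t
            p -= buf


@dataclass
class TrainHistory:
    """Per-epoch training log (running-average train loss, validation loss,
    MAE metric and the learning rate in force)."""

    loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def n_epochs(self) -> int:
        return len(self.loss)


def fit_regressor(
    model: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    lr: float = 1e-3,
    epochs_max: int = 300,
    batch_size: int = 16,
    early_stop_patience: int = 20,
    lr_reduce_factor: float = 0.5,
    lr_reduce_patience: int = 10,
    lr_min: float = 1e-6,
    restore_best: bool = True,
    seed: int = 0,
) -> TrainHistory:
    """MSE training loop with MAE metric, early stopping on validation loss
    (best weights restored) and reduce-on-plateau LR scheduling."""
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32).ravel()
    X_val = np.asarray(X_val, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32).ravel()
    if len(X_val) == 0:
        raise ValueError("validation set must be non-empty")

    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr)
    hist = TrainHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    wait_stop = 0
    wait_lr = 0
    n = len(X)

    for epoch in range(epochs_max):
        perm = rng.permutation(n)
        batch_losses, batch_maes = [], []
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            xb, yb = X[idx], y[idx]
            pred = model.forward(xb, training=True).ravel()
            err = pred - yb
            batch_losses.append(float(np.mean(err**2)))
            batch_maes.append(float(np.mean(np.abs(err))))
            dout = (2.0 * err / len(yb)).astype(np.float32)[:, None]
            model.backward(dout)
            opt.step(model.grads)

        val_pred = model.predict(X_val)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        hist.loss.append(float(np.mean(batch_losses)))
        hist.mae.append(float(np.mean(batch_maes)))
        hist.val_loss.append(val_loss)
        hist.val_mae.append(float(np.mean(np.abs(val_pred - y_val))))
        hist.lr.append(opt.lr)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            hist.best_epoch = epoch
            wait_stop = 0
            wait_lr = 0
        else:
            wait_stop += 1
            wait_lr += 1
            if wait_lr >= lr_reduce_patience:
                opt.lr = max(opt.lr * lr_reduce_factor, lr_min)
                wait_lr = 0
            if wait_stop >= early_stop_patience:
                hist.stopped_epoch = epoch
                break

    if restore_best:
        model.set_weights(best_weights)
    return hist
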