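"""Minimal convolutional-network backend (numpy).

Just enough machinery for the segment classifier: 3x3 same-padded
convolutions, ReLU, 2x2 max pooling (floor semantics), a fully connected
head with dropout, a sigmoid output trained with binary cross-entropy and
Adam.  Everything is seeded and deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense", "Dropout", "Sequential", "adam_step"]


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv2D(Layer):
    """3x3 (or kxk) convolution with same padding, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # (B, C, H, W, k, k) -> (B*H*W, C*k*k)
        b_, c_, h_, w_, _, _ = win.shape
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(b_ * h_ * w_, c_ * k * k)

    def forward(self, x, train, rng):
        self.x_shape = x.shape
        self.cols = self._cols(x)
        B, _, H, W = x.shape
        out = self.cols @ self.params[0] + self.params[1]
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        B, _, H, W = self.x_shape
        k, p = self.k, self.k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads[0][...] = self.cols.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = (dflat @ self.params[0].T).reshape(B, H, W, self.c_in, k, k)
        dxp = np.zeros((B, self.c_in, H + 2 * p, W + 2 * p))
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + H, dj:dj + W] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + H, p:p + W]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dout):
        return dout * self.mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; trailing odd row/column dropped (floor)."""

    def forward(self, x, train, rng):
        B, C, H, W = x.shape
        H2, W2 = H // 2, W // 2
        self.in_shape = x.shape
        xc = x[:, :, : 2 * H2, : 2 * W2].reshape(B, C, H2, 2, W2, 2)
        flat = xc.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
        self.arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout):
        B, C, H, W = self.in_shape
        H2, W2 = H // 2, W // 2
        dflat = np.zeros((B, C, H2, W2, 4))
        np.put_along_axis(dflat, self.arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((B, C, H, W))
        dx[:, :, : 2 * H2, : 2 * W2] = (
            dflat.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, 2 * H2, 2 * W2)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self.in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self.in_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, train, rng):
        self.x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dout):
        self.grads[0][...] = self.x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.params[0].T


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p <= 0:
            self.mask = None
            return x
        self.mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self.mask

    def backward(self, dout):
        return dout if self.mask is None else dout * self.mask


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for l in self.layers for p, g in zip(l.params, l.grads)]


def adam_step(state: dict, params_grads: list[tuple[np.ndarray, np.ndarray]],
              lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
              eps: float = 1e-8) -> None:
    """One Adam update over (param, grad) pairs; ``state`` persists moments."""
    state["t"] = state.get("t", 0) + 1
    t = state["t"]
    if "m" not in state:
        state["m"] = [np.zeros_like(p) for p, _ in params_grads]
        state["v"] = [np.zeros_like(p) for p, _ in params_grads]
    for i, (p, g) in enumerate(params_grads):
        state["m"][i] = beta1 * state["m"][i] + (1 - beta1) * g
        state["v"][i] = beta2 * state["v"][i] + (1 - beta2) * g * g
        mhat = state["m"][i] / (1 - beta1 ** t)
        vhat = state["v"][i] / (1 - beta2 ** t)
        p -= lr * mhat / (np.sqrt(vhat) + eps)
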