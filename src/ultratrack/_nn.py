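"""Minimal NumPy neural-network engine for small 3D convolutional models.

Implements exactly the layer types the autoencoder needs — 3D convolution
(3x3x3, stride 1, same padding) via im2col + GEMM, 2x average pooling,
nearest-neighbour 2x upsampling, dense layers and leaky ReLU — with manual
backpropagation and an Adam optimiser. Everything runs in float32; all
randomness flows through an injected ``numpy.random.Generator``.

Volumetric tensors are laid out channels-last, ``(N, D, H, W, C)``: the
im2col gather and its transposed scatter then move C-contiguous blocks and
never permute axes, which is what keeps a pure-NumPy training loop fast on
one CPU. Dense layers use ``(N, features)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Layer", "Conv3d", "AvgPool3d", "Upsample3d", "Dense", "LeakyReLU",
    "Flatten", "Reshape", "Sequential", "Adam",
]


class Layer:
    """Base layer: stateless unless it holds parameters."""

    trainable: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


@njit(cache=True)
def _im2col_3(xp: np.ndarray, col: np.ndarray, d: int, h: int, w: int, c: int) -> None:
    """Gather 3x3x3 neighbourhoods into (N*DHW, 27*C) columns, one pass.

    Writes are contiguous per lattice site and reads stay cache-local, which
    is what a strided NumPy slice loop cannot achieve.
    """
    n = xp.shape[0]
    for a in range(n):
        m = a * d * h * w
        for x in range(d):
            for y in range(h):
                for z in range(w):
                    q = 0
                    for i in range(3):
                        for j in range(3):
                            for k in range(3):
                                for cc in range(c):
                                    col[m, q] = xp[a, x + i, y + j, z + k, cc]
                                    q += 1
                    m += 1


@njit(cache=True)
def _col2im_3(dxp: np.ndarray, dcol: np.ndarray, d: int, h: int, w: int, c: int) -> None:
    """Transposed gather: scatter-add column gradients back onto the padded grid."""
    n = dxp.shape[0]
    for a in range(n):
        m = a * d * h * w
        for x in range(d):
            for y in range(h):
                for z in range(w):
                    q = 0
                    for i in range(3):
                        for j in range(3):
                            for k in range(3):
                                for cc in range(c):
                                    dxp[a, x + i, y + j, z + k, cc] += dcol[m, q]
                                    q += 1
                    m += 1


class Conv3d(Layer):
    """3x3x3 convolution, stride 1, zero padding 1 (shape-preserving)."""

    K = 3

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 activation_gain: float = 2.0):
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * self.K**3
        std = np.sqrt(activation_gain / fan_in)
        # Weight stored flat as (27 * C_in, C_out), kernel-offset major /
        # input-channel minor, matching the im2col column layout.
        self.W = (std * rng.standard_normal((fan_in, c_out))).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # Scratch buffers reused across calls (first-touch page faults on
        # fresh multi-hundred-MB allocations would dominate the runtime).
        self._bufs: dict[tuple, dict[str, np.ndarray]] = {}
        self._shape: tuple | None = None

    def _scratch(self, shape: tuple) -> dict[str, np.ndarray]:
        buf = self._bufs.get(shape)
        if buf is None:
            n, d, h, w, c = shape
            m = n * d * h * w
            buf = {
                "xp": np.zeros((n, d + 2, h + 2, w + 2, c), dtype=np.float32),
                "col": np.empty((m, self.K**3 * c), dtype=np.float32),
                "out": np.empty((m, self.c_out), dtype=np.float32),
                "dcol": np.empty((m, self.K**3 * c), dtype=np.float32),
                "dxp": np.empty((n, d + 2, h + 2, w + 2, c), dtype=np.float32),
                "dx": np.empty((n, d, h, w, c), dtype=np.float32),
            }
            self._bufs.clear()  # keep at most one batch geometry resident
            self._bufs[shape] = buf
        return buf

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        buf = self._scratch(x.shape)
        xp = buf["xp"]
        xp[:, 1:-1, 1:-1, 1:-1, :] = x  # borders stay zero
        self._shape = x.shape
        colm = buf["col"]
        _im2col_3(xp, colm, d, h, w, c)
        out = buf["out"]
        np.matmul(colm, self.W, out=out)
        out += self.b
        return out.reshape(n, d, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._shape
        buf = self._scratch(self._shape)
        dy_mat = dy.reshape(-1, self.c_out)
        colm = buf["col"]
        # (dy.T @ col).T hits the fast row-major GEMM path
        self.dW[...] = (dy_mat.T @ colm).T
        self.db[...] = dy_mat.sum(axis=0)
        dcol = buf["dcol"]
        if self.c_out == 1:
            # (M, 1) @ (1, K) degenerates to a broadcast outer product.
            np.multiply(dy_mat, self.W[:, 0], out=dcol)
        else:
            np.matmul(dy_mat, self.W.T, out=dcol)
        dxp = buf["dxp"]
        dxp[...] = 0.0
        _col2im_3(dxp, dcol, d, h, w, c)
        dx = buf["dx"]
        np.copyto(dx, dxp[:, 1:-1, 1:-1, 1:-1, :])
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def __deepcopy__(self, memo):
        new = object.__new__(Conv3d)
        new.c_in, new.c_out = self.c_in, self.c_out
        new.W, new.b = self.W.copy(), self.b.copy()
        new.dW, new.db = np.zeros_like(self.W), np.zeros_like(self.b)
        new.trainable = self.trainable
        new._bufs, new._shape = {}, None  # scratch is never copied
        return new


class AvgPool3d(Layer):
    """Non-overlapping 2x2x2 average pooling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4, 6))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        up = dy.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
        return (up / 8.0).astype(np.float32)


class Upsample3d(Layer):
    """Nearest-neighbour 2x upsampling on every spatial axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = dy.shape
        return dy.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4, 6))


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation_gain: float = 2.0):
        std = np.sqrt(activation_gain / n_in)
        self.W = (std * rng.standard_normal((n_in, n_out))).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        self._x = None
        return dy @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.slope * dy, dy)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Reshape(Layer):
    """(N, prod(shape)) <-> (N, *shape)."""

    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(dy.shape[0], -1)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params(self, trainable_only: bool = False) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            out.extend(layer.params())
        return out

    def grads(self, trainable_only: bool = False) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            out.extend(layer.grads())
        return out

    def state(self) -> list[np.ndarray]:
        """Copies of every parameter (for checkpointing / best-weight restore)."""
        return [p.copy() for p in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(state):
            raise ValueError("state length mismatch")
        for p, s in zip(own, state):
            if p.shape != s.shape:
                raise ValueError(f"parameter shape mismatch: {p.shape} vs {s.shape}")
            p[...] = s


class Adam:
    """Adam over an explicit parameter list; grads are read in lock-step."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
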