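"""Compact reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the convolutional-LSTM
autoencoder: broadcast arithmetic, matmul, gated activations, slicing,
padding, valid cross-correlation in 1-D and 2-D, stacking and mean
reduction. Gradients are checked against central finite differences in the
test suite.

Conventions
-----------
* Every :class:`Tensor` participates in the graph; call ``loss.backward()``
  on a scalar to populate ``.grad`` on all ancestors.
* Forward values are float64 throughout; determinism follows from
  single-threaded numpy on fixed seeds.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes introduced or expanded by broadcasting."""
    extra = grad.ndim - len(shape)
    for _ in range(extra):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph traversal ---------------------------------------------------

    def backward(self) -> None:
        """Reverse-accumulate gradients from this scalar."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # Copy: the incoming array may alias another node's gradient, and
            # slice-indexed children later add into this buffer in place.
            self.grad = np.array(grad)
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def bwd(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, (self, other), bwd)

    def __sub__(self, other: "Tensor") -> "Tensor":
        out_data = self.data - other.data

        def bwd(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(-_unbroadcast(g, other.data.shape))

        return Tensor(out_data, (self, other), bwd)

    def __mul__(self, other: "Tensor") -> "Tensor":
        out_data = self.data * other.data

        def bwd(g: np.ndarray) -> None:
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, (self, other), bwd)

    def __matmul__(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def bwd(g: np.ndarray) -> None:
            self._accumulate(
                _unbroadcast(g @ other.data.swapaxes(-1, -2), self.data.shape)
            )
            other._accumulate(
                _unbroadcast(self.data.swapaxes(-1, -2) @ g, other.data.shape)
            )

        return Tensor(out_data, (self, other), bwd)

    def __getitem__(self, idx) -> "Tensor":
        """Basic (slice/integer) indexing only — no fancy index arrays."""
        out_data = self.data[idx]

        def bwd(g: np.ndarray) -> None:
            # In-place accumulation into a shared buffer: slicing the same
            # tensor many times (e.g. per LSTM timestep) must not allocate a
            # full-size gradient per slice.
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad[idx] += g

        return Tensor(out_data, (self,), bwd)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        out_data = self.data.reshape(shape)

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g.reshape(self.data.shape))

        return Tensor(out_data, (self,), bwd)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        out_data = self.data.transpose(axes)
        inverse = np.argsort(axes)

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g.transpose(inverse))

        return Tensor(out_data, (self,), bwd)

    # -- activations -------------------------------------------------------

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, (self,), bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g: np.ndarray) -> None:
            self._accumulate(g * (1.0 - out_data * out_data))

        return Tensor(out_data, (self,), bwd)

    def square(self) -> "Tensor":
        def bwd(g: np.ndarray) -> None:
            self._accumulate(2.0 * g * self.data)

        return Tensor(self.data * self.data, (self,), bwd)

    def mean(self) -> "Tensor":
        n = self.data.size

        def bwd(g: np.ndarray) -> None:
            self._accumulate(np.full_like(self.data, float(g) / n))

        return Tensor(self.data.mean(), (self,), bwd)


def pad(x: Tensor, pad_width: Sequence[tuple[int, int]]) -> Tensor:
    """Zero-pad; ``pad_width`` as in :func:`numpy.pad`."""
    out_data = np.pad(x.data, pad_width)
    slices = tuple(
        slice(lo, lo + n) for (lo, _), n in zip(pad_width, x.data.shape)
    )

    def bwd(g: np.ndarray) -> None:
        x._accumulate(g[slices])

    return Tensor(out_data, (x,), bwd)


def flip(x: Tensor, axis: int) -> Tensor:
    def bwd(g: np.ndarray) -> None:
        x._accumulate(np.flip(g, axis=axis))

    return Tensor(np.flip(x.data, axis=axis), (x,), bwd)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g: np.ndarray) -> None:
        parts = np.moveaxis(g, axis, 0)
        for t, part in zip(tensors, parts):
            t._accumulate(part)

    return Tensor(out_data, tuple(tensors), bwd)


def conv1d(x: Tensor, w: Tensor) -> Tensor:
    """Valid cross-correlation along axis 1.

    ``x``: (B, L, C_in); ``w``: (K, C_in, C_out) -> (B, L-K+1, C_out).
    """
    K = w.data.shape[0]
    win = sliding_window_view(x.data, K, axis=1)  # (B, Lout, Cin, K)
    out_data = np.einsum("blck,kco->blo", win, w.data)

    def bwd(g: np.ndarray) -> None:
        w._accumulate(np.einsum("blck,blo->kco", win, g))
        gpad = np.pad(g, ((0, 0), (K - 1, K - 1), (0, 0)))
        gwin = sliding_window_view(gpad, K, axis=1)  # (B, L, Cout, K)
        x._accumulate(np.einsum("btok,kco->btc", gwin, w.data[::-1]))

    return Tensor(out_data, (x, w), bwd)


def conv2d(x: Tensor, w: Tensor) -> Tensor:
    """Valid 2-D cross-correlation, single input/output channel.

    ``x``: (B, H, W); ``w``: (Kh, Kw) -> (B, H-Kh+1, W-Kw+1).
    """
    kh, kw = w.data.shape
    win = sliding_window_view(x.data, (kh, kw), axis=(1, 2))  # (B,Ho,Wo,Kh,Kw)
    out_data = np.einsum("bhwij,ij->bhw", win, w.data)

    def bwd(g: np.ndarray) -> None:
        w._accumulate(np.einsum("bhwij,bhw->ij", win, g))
        gpad = np.pad(g, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gwin = sliding_window_view(gpad, (kh, kw), axis=(1, 2))
        x._accumulate(np.einsum("bhwij,ij->bhw", gwin, w.data[::-1, ::-1]))

    return Tensor(out_data, (x, w), bwd)


def conv_transpose2d(x: Tensor, w: Tensor) -> Tensor:
    """Stride-1, no-padding 2-D transposed convolution (single channel).

    Output size grows: (B, H, W) -> (B, H+Kh-1, W+Kw-1). Realized as full
    cross-correlation with the flipped kernel.
    """
    kh, kw = w.data.shape
    padded = pad(x, ((0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
    return conv2d(padded, flip(flip(w, 0), 1))


def conv_transpose1d(x: Tensor, w: Tensor) -> Tensor:
    """Stride-1, no-padding 1-D transposed convolution along axis 1.

    ``x``: (B, L, C_in); ``w``: (K, C_out, C_in) -> (B, L+K-1, C_out).
    Realized as full cross-correlation with the kernel flipped along K and
    its channel axes swapped.
    """
    K = w.data.shape[0]
    padded = pad(x, ((0, 0), (K - 1, K - 1), (0, 0)))
    return conv1d(padded, flip(w, 0).transpose((0, 2, 1)))


class Adam:
    """Adaptive-moment gradient descent on a list of parameter tensors."""

    def __init__(
        self,
        params: Sequence[Tensor],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
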