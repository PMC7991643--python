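"""Minimal reverse-mode automatic differentiation for small conv-nets.

A deliberately small tape-based engine on NumPy arrays (NCHW layout)
providing exactly the operations the image translator needs: 2-D
convolution (im2col via stride tricks), nearest-neighbour upsampling,
channel concatenation, leaky-ReLU / tanh nonlinearities, elementwise
arithmetic and scalar reductions, plus an Adam optimizer.  Gradients
are accumulated by reverse topological traversal of the recorded graph.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter", "Adam", "DTYPE"]

#: default floating dtype for network parameters and activations;
#: single precision is ample for the losses used here
DTYPE = np.float32


class Tensor:
    """A node in the autodiff graph wrapping a floating ndarray.

    The dtype of the input array is preserved (integers are promoted to
    :data:`DTYPE`), so graphs can be run in float64 when exact gradient
    checks are wanted.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(DTYPE)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _coerce(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    # -- elementwise ops ---------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        if other.data.shape not in ((), self.data.shape):
            raise ValueError("add requires equal shapes or a scalar")

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g if other.data.shape else np.array(g.sum()))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    def __sub__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(-g if other.data.shape else np.array(-g.sum()))

        return Tensor(self.data - other.data, parents=(self, other), backward=bwd)

    def scale(self, c: float):
        c = self.data.dtype.type(c)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * c)

        return Tensor(self.data * c, parents=(self,), backward=bwd)

    # -- nonlinearities ----------------------------------------------------
    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.where(mask, 1.0, slope))

        return Tensor(
            np.where(mask, self.data, slope * self.data),
            parents=(self,),
            backward=bwd,
        )

    def tanh(self):
        out = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out * out))

        return Tensor(out, parents=(self,), backward=bwd)

    # -- reductions --------------------------------------------------------
    def mean_abs(self):
        n = self.data.size
        sign = np.sign(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(float(g) * sign / n)

        return Tensor(np.abs(self.data).mean(), parents=(self,), backward=bwd)

    def mean_sq(self):
        n = self.data.size

        def bwd(g):
            if self.requires_grad:
                self._accumulate(float(g) * 2.0 * self.data / n)

        return Tensor((self.data**2).mean(), parents=(self,), backward=bwd)

    # -- structural ops ----------------------------------------------------
    def concat(self, other: "Tensor"):
        """Concatenate along the channel axis (axis 1)."""
        c0 = self.data.shape[1]

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g[:, :c0])
            if other.requires_grad:
                other._accumulate(g[:, c0:])

        return Tensor(
            np.concatenate([self.data, other.data], axis=1),
            parents=(self, other),
            backward=bwd,
        )

    def upsample2(self):
        """Nearest-neighbour 2x spatial upsampling."""
        out = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def bwd(g):
            if self.requires_grad:
                n, c, h2, w2 = g.shape
                self._accumulate(
                    g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                )

        return Tensor(out, parents=(self,), backward=bwd)

    def conv2d(self, weight: "Tensor", bias: "Tensor", stride: int = 1, pad: int = 0):
        """2-D cross-correlation, zero padding, NCHW x (O,C,kh,kw).

        Lowered to matrix products on an im2col buffer; the buffer is
        materialized once in the forward pass and reused for the weight
        gradient, and the input gradient is scattered back with one
        strided addition per kernel tap (col2im).
        """
        x = self.data
        w = weight.data
        o, cin, kh, kw = w.shape
        s = stride
        n, _, h, wdt = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        # (N, Ho, Wo, C*kh*kw) contiguous buffer
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, cin * kh * kw
        )
        w_mat = w.reshape(o, -1)
        out = (cols @ w_mat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
        out = out + bias.data[None, :, None, None]

        def bwd(g):
            g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o)
            if weight.requires_grad:
                weight._accumulate((g_mat.T @ cols).reshape(w.shape))
            if bias.requires_grad:
                bias._accumulate(g_mat.sum(axis=0))
            if self.requires_grad:
                dcols = (g_mat @ w_mat).reshape(n, ho, wo, cin, kh, kw)
                dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # N,C,Ho,Wo,kh,kw
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dcols[
                            :, :, :, :, i, j
                        ]
                self._accumulate(
                    gxp[:, :, pad : pad + h, pad : pad + wdt]
                    if pad
                    else gxp
                )

        return Tensor(out, parents=(self, weight, bias), backward=bwd)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def he_init(
    rng: np.random.Generator, shape, fan_in: int, dtype=None
) -> Parameter:
    w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)
    return Parameter(w.astype(dtype or DTYPE))


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            p.data -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps
            )
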