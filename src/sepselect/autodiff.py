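"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the operator set the package's networks need:
broadcast arithmetic, (batched) matrix products, the usual pointwise
nonlinearities, reductions, slicing/concatenation, a fused causal dilated
1-D convolution and time pooling for the temporal convolutional network,
and a numerically stabilised softmax. Gradients are accumulated by
topological sort over the tape; ``Tensor.detach`` cuts the tape, which is
how the reinforcement reward is treated as a constant.

All computation is float64: the training loop asserts loss-algebra
identities to 1e-9 at every step, which float32 cannot honour.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "Parameter", "concat", "stack_rows", "Adam", "SGD"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus a gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward
        self._grad_borrowed = False

    # ------------------------------------------------------------------ utils
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        # first contribution borrows the incoming buffer (no copy); a second
        # contribution must allocate, since the borrowed array may be shared
        if self.grad is None:
            if g.shape != self.data.shape:
                g = np.broadcast_to(g, self.data.shape)
            self.grad = g
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + g
            self._grad_borrowed = False
        else:
            self.grad += g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (long training tapes)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = bwd
        return out

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data / other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(
                    -g * self.data / (other.data * other.data), other.shape))
        out._backward = bwd
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        e = float(exponent)
        out = Tensor(self.data ** e, requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))
        out._backward = bwd
        return out

    # ------------------------------------------------------------- pointwise
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out.data)
        out._backward = bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = bwd
        return out

    def sigmoid(self) -> "Tensor":
        s = expit(self.data)
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))
        out._backward = bwd
        return out

    def silu(self) -> "Tensor":
        s = expit(self.data)
        out = Tensor(self.data * s, requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (s * (1.0 + self.data * (1.0 - s))))
        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes through only inside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi),
                     requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)
        out._backward = bwd
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy()
                            if np.ndim(g) else np.full(self.shape, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1) -> "Tensor":
        """Fused, max-shifted softmax along `axis`."""
        e = np.exp(self.data - self.data.max(axis=axis, keepdims=True))
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))
        out._backward = bwd
        return out

    # ---------------------------------------------------------- shape surgery
    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape),
                     requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))
        out._backward = bwd
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b),
                     requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))
        out._backward = bwd
        return out

    @property
    def T(self) -> "Tensor":
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = bwd
        return out

    # -------------------------------------------------------- temporal layers
    def causal_conv1d(self, weight: "Tensor", bias: "Tensor",
                      dilation: int = 1) -> "Tensor":
        """Causal dilated 1-D convolution.

        self: (B, Cin, T); weight: (Cout, Cin, K); bias: (Cout,).
        Output (B, Cout, T); out[:, :, t] only depends on inputs at times <= t.
        The left pad of (K-1)*dilation replicates the first observation, so a
        time-constant series maps to a time-constant output (no edge artefact).
        """
        x = self.data
        B, Cin, T = x.shape
        Cout, Cin_w, K = weight.shape
        if Cin_w != Cin:
            raise ValueError(f"channel mismatch: input {Cin}, weight {Cin_w}")
        pad = (K - 1) * dilation
        xp = np.concatenate([np.repeat(x[:, :, :1], pad, axis=2), x], axis=2)
        # columns (B, T, Cin*K): tap k sees time t + k*dilation in padded frame,
        # i.e. original time t - (K-1-k)*dilation
        cols = np.concatenate(
            [xp[:, :, k * dilation:k * dilation + T] for k in range(K)], axis=1)
        cols = cols.transpose(0, 2, 1).reshape(B * T, Cin * K)
        # cols columns are tap-major ([tap0 ch0..chCin-1 | tap1 ...]); match it
        wmat = weight.data.transpose(0, 2, 1).reshape(Cout, K * Cin).T
        y = (cols @ wmat).reshape(B, T, Cout).transpose(0, 2, 1) + \
            bias.data[None, :, None]
        out = Tensor(y, requires_grad=(self.requires_grad or weight.requires_grad
                                       or bias.requires_grad),
                     parents=(self, weight, bias))

        def bwd(g):
            go = g.transpose(0, 2, 1).reshape(B * T, Cout)
            if weight.requires_grad:
                weight._accum(self._conv_weight_grad(go, cols, Cout, Cin, K))
            if bias.requires_grad:
                bias._accum(go.sum(axis=0))
            if self.requires_grad:
                gcols = (go @ wmat.T).reshape(B, T, Cin * K).transpose(0, 2, 1)
                gxp = np.zeros((B, Cin, T + pad))
                for k in range(K):
                    gxp[:, :, k * dilation:k * dilation + T] += \
                        gcols[:, k * Cin:(k + 1) * Cin, :]
                gx = gxp[:, :, pad:].copy()
                if pad:   # replicated pad region feeds back into t = 0
                    gx[:, :, 0] += gxp[:, :, :pad].sum(axis=2)
                self._accum(gx)
        out._backward = bwd
        return out

    @staticmethod
    def _conv_weight_grad(go: np.ndarray, cols: np.ndarray,
                          Cout: int, Cin: int, K: int) -> np.ndarray:
        gw = cols.T @ go                       # (Cin*K, Cout)
        gw = gw.reshape(K, Cin, Cout)          # axis-1 blocks are taps
        return gw.transpose(2, 1, 0)           # (Cout, Cin, K)

    def avg_pool_time(self, window: int = 2) -> "Tensor":
        """Non-overlapping average pooling over the last (time) axis.

        A ragged tail shorter than `window` is averaged over its true length.
        """
        x = self.data
        B, C, T = x.shape
        n_full = T // window
        pieces = []
        if n_full:
            pieces.append(x[:, :, :n_full * window]
                          .reshape(B, C, n_full, window).mean(axis=3))
        tail = T - n_full * window
        if tail:
            pieces.append(x[:, :, n_full * window:].mean(axis=2, keepdims=True))
        y = np.concatenate(pieces, axis=2)
        out = Tensor(y, requires_grad=self.requires_grad, parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(x)
            if n_full:
                gx[:, :, :n_full * window] = np.repeat(
                    g[:, :, :n_full] / window, window, axis=2)
            if tail:
                gx[:, :, n_full * window:] = g[:, :, n_full:n_full + 1] / tail
            self._accum(gx)
        out._backward = bwd
        return out


class Parameter(Tensor):
    """A trainable tensor (requires_grad always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    out._backward = bwd
    return out


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Stack 1-D tensors into a 2-D tensor along a new leading axis."""
    out = Tensor(np.stack([t.data for t in tensors], axis=0),
                 requires_grad=any(t.requires_grad for t in tensors),
                 parents=tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(g[i])
    out._backward = bwd
    return out


# ---------------------------------------------------------------- optimizers
class SGD:
    """Plain stochastic gradient descent over a parameter list."""

    def __init__(self, params: Iterable[Parameter], lr: float = 0.01):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam:
    """Adam with bias correction (Kingma & Ba defaults for the moments)."""

    def __init__(self, params: Iterable[Parameter], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
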