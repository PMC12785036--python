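"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the encoder needs are implemented: broadcasting
arithmetic, batched matmul, reshape/transpose, embedding lookup, GELU,
fused layer norm, fused masked softmax, dropout and a fused weighted
softmax cross-entropy.  Gradients are checked against central finite
differences in the test suite.

Arrays are kept in float32 unless float64 input is supplied (the
gradient checks run in float64).
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "embedding", "layer_norm", "masked_softmax", "gelu",
           "dropout", "weighted_cross_entropy_logits"]


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple["Tensor", ...] = (),
                 _backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = fwd(self.data, other.data)
        out = Tensor(out_data, _parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(bwd_self(g), self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(bwd_other(g), other.shape))

        out._backward = backward
        return out

    def __add__(self, other) -> "Tensor":
        return self._binary(other, lambda a, b: a + b,
                            lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other) -> "Tensor":
        return self._binary(other, lambda a, b: a - b,
                            lambda g: g, lambda g: -g)

    def __mul__(self, other) -> "Tensor":
        other_t = other if isinstance(other, Tensor) else Tensor(other)
        return self._binary(other_t, lambda a, b: a * b,
                            lambda g: g * other_t.data,
                            lambda g: g * self.data)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __matmul__(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data
        out = Tensor(out_data, _parents=(self, other))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                a = self.data
                if a.ndim == 1:  # vector @ matrix
                    gb = np.outer(a, g)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes: int) -> "Tensor":
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = np.argsort(axes)

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def cls_pool(self) -> "Tensor":
        """Select position 0 along axis 1: (B, T, D) -> (B, D)."""
        out = Tensor(self.data[:, 0, :], _parents=(self,))

        def backward(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, 0, :] = g
                self._accumulate(full)

        out._backward = backward
        return out


# -- fused ops ---------------------------------------------------------------


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    out = Tensor(table.data[ids], _parents=(table,))

    def backward(g: np.ndarray) -> None:
        if table.requires_grad:
            grad = np.zeros_like(table.data)
            np.add.at(grad, ids.reshape(-1),
                      g.reshape(-1, table.data.shape[-1]))
            table._accumulate(grad)

    out._backward = backward
    return out


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, exact (erf) form."""
    u = x.data / np.sqrt(2.0)
    cdf = 0.5 * (1.0 + erf(u))
    out = Tensor(x.data * cdf, _parents=(x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            pdf = np.exp(-0.5 * x.data * x.data) / np.sqrt(2.0 * np.pi)
            x._accumulate(g * (cdf + x.data * pdf))

    out._backward = backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gamma.data + beta.data, _parents=(x, gamma, beta))

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accumulate(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gh = g * gamma.data
            term1 = gh
            term2 = gh.mean(axis=-1, keepdims=True)
            term3 = xhat * (gh * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (term1 - term2 - term3))

    out._backward = backward
    return out


def masked_softmax(scores: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Softmax over the last axis after adding ``additive_mask`` (0 / -inf)."""
    z = scores.data if additive_mask is None else scores.data + additive_mask
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, _parents=(scores,))

    def backward(g: np.ndarray) -> None:
        if scores.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            scores._accumulate(p * (g - dot))

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    keep = keep.astype(x.data.dtype)
    out = Tensor(x.data * keep, _parents=(x,))

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(g * keep)

    out._backward = backward
    return out


def weighted_cross_entropy_logits(logits: Tensor, labels: np.ndarray,
                                  class_weights: np.ndarray) -> Tensor:
    """Weight-normalized mean of per-example weighted cross-entropy.

    loss = sum_i w_{y_i} * (-log p_{i, y_i}) / sum_i w_{y_i}, with p
    from a max-shifted softmax of the logits.
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = len(labels)
    w = class_weights[labels]
    logp = z[np.arange(n), labels] - np.log(e.sum(axis=-1))
    wsum = w.sum()
    loss = -(w * logp).sum() / wsum
    out = Tensor(np.asarray(loss, dtype=logits.data.dtype),
                 _parents=(logits,))

    def backward(g: np.ndarray) -> None:
        if logits.requires_grad:
            onehot = np.zeros_like(p)
            onehot[np.arange(n), labels] = 1.0
            grad = (w[:, None] / wsum) * (p - onehot)
            logits._accumulate(g * grad)

    out._backward = backward
    return out


def parameters_norm(params: Iterable[Tensor]) -> float:
    return float(np.sqrt(sum(float((p.data ** 2).sum()) for p in params)))
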