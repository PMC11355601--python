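"""Minimal reverse-mode automatic differentiation over numpy float32 arrays.

A :class:`Tensor` wraps an ndarray together with the closure needed to
propagate gradients to its parents.  The engine is deliberately small: it
supports exactly the operations the package's networks need, every operation
lives in :mod:`dermadapt.nn.functional`, and every backward rule is checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


class Tensor:
    """An ndarray node in a dynamically built computation graph.

    Parameters
    ----------
    data:
        Array payload; always stored as contiguous ``float32``.
    requires_grad:
        Whether gradients should be accumulated into ``.grad``.
    parents:
        The tensors this node was computed from.
    backward_fn:
        Closure mapping the upstream gradient (an ndarray shaped like
        ``data``) to a tuple of gradients aligned with ``parents``; entries
        for parents that do not require grad may be ``None``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad=False, parents=(), backward_fn=None):
        arr = np.asarray(data, dtype=np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in tensor payload")
        # ascontiguousarray promotes 0-d to 1-d; keep scalars 0-d
        self.data = arr if arr.ndim == 0 else np.ascontiguousarray(arr)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    # -- autodiff ----------------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, upstream=None):
        """Run reverse-mode accumulation from this node.

        ``upstream`` defaults to 1 for scalar outputs (loss values).
        """
        if upstream is None:
            if self.data.size != 1:
                raise ValueError("backward() without an upstream gradient "
                                 "requires a scalar tensor")
            upstream = np.ones_like(self.data)
        upstream = np.asarray(upstream, dtype=np.float32)
        if upstream.shape != self.data.shape:
            raise ValueError(
                f"upstream gradient shape {upstream.shape} does not match "
                f"tensor shape {self.data.shape}")

        order = _topological_order(self)
        grads: dict[int, np.ndarray] = {id(self): upstream}
        for node in order:
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward_fn is None:
                # leaf parameter / input
                node.grad = g if node.grad is None else node.grad + g
            if node._backward_fn is None:
                continue
            parent_grads = node._backward_fn(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                pg = np.asarray(pg, dtype=np.float32)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


def _topological_order(root: Tensor) -> list[Tensor]:
    """Reverse topological order (root first) via iterative DFS."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
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
            if id(p) not in seen and p.requires_grad:
                stack.append((p, False))
    order.reverse()
    return order


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
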