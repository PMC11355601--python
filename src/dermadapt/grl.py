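"""Gradient reversal layer (GRL).

The GRL is the operator that turns adversarial feature alignment into a
single-optimiser problem: on the forward pass it is the identity, on the
backward pass it multiplies the incoming gradient by ``-λ``.  Placed between
the feature extractor and the domain classifier, it lets one backward pass
simultaneously train the domain classifier to *minimise* domain-classification
error and the feature extractor to *maximise* it.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Tensor, as_tensor
from .nn import functional as F

__all__ = ["GRLCoefficient", "grl_forward", "grl_backward", "gradient_reversal"]


class GRLCoefficient:
    """Mutable holder for the reversal strength λ ≥ 0.

    A schedule can assign ``coeff.value`` between optimisation steps; the
    operator reads the holder at backward time, so the computation graph never
    needs rebuilding.
    """

    __slots__ = ("_value",)

    def __init__(self, value: float = 1.0):
        self._value = 0.0
        self.value = value

    @property
    def value(self) -> float:
        return self._value

    @value.setter
    def value(self, v: float):
        v = float(v)
        if not math.isfinite(v) or v < 0.0:
            raise ValueError(f"lambda must be a finite non-negative real, got {v}")
        self._value = v

    def __repr__(self):
        return f"GRLCoefficient({self._value})"


def gradient_reversal(x: Tensor, coeff: GRLCoefficient) -> Tensor:
    """Apply the GRL inside an autodiff graph (identity / backward ``-λ``)."""
    return F.gradient_reversal(x, coeff)


def grl_forward(x, coeff: GRLCoefficient) -> np.ndarray:
    """Forward pass: the identity map, independent of λ.

    Raises ``ValueError`` on non-finite input (invalid activations).
    """
    arr = np.asarray(x, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite activations passed to the GRL")
    del coeff  # λ plays no role in the forward value
    return arr


def grl_backward(upstream_grad, coeff: GRLCoefficient,
                 forward_shape=None) -> np.ndarray:
    """Backward pass: ``-λ`` times the upstream gradient, elementwise."""
    g = np.asarray(upstream_grad, dtype=np.float32)
    if forward_shape is not None and tuple(g.shape) != tuple(forward_shape):
        raise ValueError(
            f"gradient shape {g.shape} does not match forward input shape "
            f"{tuple(forward_shape)}")
    return (-coeff.value) * g
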