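"""Layer/module abstractions on top of the functional ops.

Determinism model
-----------------
Every parameterised layer is constructed with a *name* and a *seed*; its
initial weights come from ``seed_rng(seed, name)``.  Stochastic forward
behaviour (dropout) draws from a stateless stream keyed by
``(seed, step, call_tag, layer_name)`` supplied through a
:class:`ForwardContext`, so two models that share a sub-network and a seed
produce bit-identical randomness on the shared path regardless of what else
they compute.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "seed_rng", "stream_key", "ForwardContext", "Module", "Sequential",
    "Linear", "Conv2d", "ConvTranspose2d", "BatchNorm", "Dropout",
    "ReLU", "LeakyReLU", "Sigmoid", "Softmax", "MaxPool2d", "Flatten",
]


def stream_key(tag) -> int:
    """Stable 32-bit key for a string tag (used in SeedSequence spawns)."""
    return zlib.crc32(str(tag).encode("utf-8"))


def seed_rng(seed: int, *tags) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF] + [stream_key(t) if isinstance(t, str)
                                          else int(t) for t in tags]
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(entropy)))


@dataclass
class ForwardContext:
    """Per-call forward state: train/eval switch and the dropout stream.

    ``tag`` distinguishes multiple forward calls within one optimisation step
    (e.g. the source and target halves of an adversarial step).

    ``bn_stats`` selects batch-norm behaviour during training: ``"batch"``
    (this batch's statistics; running buffers updated), ``"batch_nobuf"``
    (this batch's statistics; buffers untouched — used for passes that must
    not perturb the buffers, e.g. the source-only class pass of an
    adversarial step) or ``"reuse"`` (the statistics cached by the previous
    ``"batch"``-mode call, treated as constants — used to anchor a fake
    batch to the real batch's normalisation in GAN training).
    """
    train: bool = False
    seed: int = 0
    step: int = 0
    tag: int = 0
    bn_stats: str = "batch"

    def rng(self, layer_name: str) -> np.random.Generator:
        return seed_rng(self.seed, self.step, self.tag, stream_key(layer_name))


EVAL_CTX = ForwardContext(train=False)


class Module:
    """Base class: tracks parameters, buffers and child modules by name."""

    def __init__(self, name: str):
        self.name = name
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: list["Module"] = []

    # -- registration ------------------------------------------------------
    def add_param(self, key: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[key] = t
        return t

    def add_buffer(self, key: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float32)
        self._buffers[key] = arr
        return arr

    def add_child(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    # -- traversal ---------------------------------------------------------
    def named_parameters(self):
        for key, t in self._params.items():
            yield f"{self.name}.{key}", t
        for child in self._children:
            yield from child.named_parameters()

    def parameters(self):
        return [t for _, t in self.named_parameters()]

    def named_buffers(self):
        for key, b in self._buffers.items():
            yield f"{self.name}.{key}", b
        for child in self._children:
            yield from child.named_buffers()

    # -- serialisation -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: t.data.copy() for k, t in self.named_parameters()}
        state.update({k: b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.named_parameters():
            if k not in state:
                raise KeyError(f"missing parameter '{k}' in state dict")
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for '{k}': "
                                 f"{arr.shape} vs {t.data.shape}")
            t.data = np.ascontiguousarray(arr)
        for k, b in self.named_buffers():
            if k not in state:
                raise KeyError(f"missing buffer '{k}' in state dict")
            b[...] = state[k]

    def __call__(self, x: Tensor, ctx: ForwardContext = EVAL_CTX) -> Tensor:
        return self.forward(x, ctx)

    def forward(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, name: str, layers):
        super().__init__(name)
        self.layers = list(layers)
        for layer in self.layers:
            self.add_child(layer)

    def forward(self, x, ctx):
        for layer in self.layers:
            x = layer(x, ctx)
        return x


class Linear(Module):
    def __init__(self, name, in_features, out_features, seed, init_std=None):
        super().__init__(name)
        rng = seed_rng(seed, name)
        std = init_std if init_std is not None else np.sqrt(2.0 / in_features)
        self.weight = self.add_param(
            "weight", rng.normal(0.0, std, (in_features, out_features)))
        self.bias = self.add_param("bias", np.zeros(out_features))

    def forward(self, x, ctx):
        return F.linear(x, self.weight, self.bias)


class Conv2d(Module):
    """Convolution on channels-last input; weight stored (kh, kw, cin, cout)."""

    def __init__(self, name, in_ch, out_ch, kernel, seed, stride=1, pad=0,
                 init_std=None):
        super().__init__(name)
        rng = seed_rng(seed, name)
        fan_in = in_ch * kernel * kernel
        std = init_std if init_std is not None else np.sqrt(2.0 / fan_in)
        self.stride, self.pad = stride, pad
        self.weight = self.add_param(
            "weight", rng.normal(0.0, std, (kernel, kernel, in_ch, out_ch)))
        self.bias = self.add_param("bias", np.zeros(out_ch))

    def forward(self, x, ctx):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose2d(Module):
    """Transposed convolution, channels-last; weight (cin, kh, kw, cout)."""

    def __init__(self, name, in_ch, out_ch, kernel, seed, stride=1, pad=0,
                 init_std=None):
        super().__init__(name)
        rng = seed_rng(seed, name)
        std = init_std if init_std is not None else \
            np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.stride, self.pad = stride, pad
        self.weight = self.add_param(
            "weight", rng.normal(0.0, std, (in_ch, kernel, kernel, out_ch)))
        self.bias = self.add_param("bias", np.zeros(out_ch))

    def forward(self, x, ctx):
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.pad)


class BatchNorm(Module):
    """Works on (n, f) and (n, c, h, w) input alike."""

    def __init__(self, name, num_features, momentum=0.1, eps=1e-5):
        super().__init__(name)
        self.momentum, self.eps = momentum, eps
        self.gamma = self.add_param("gamma", np.ones(num_features))
        self.beta = self.add_param("beta", np.zeros(num_features))
        self.running_mean = self.add_buffer("running_mean",
                                            np.zeros(num_features))
        self.running_var = self.add_buffer("running_var",
                                           np.ones(num_features))
        self._stats_cache: dict = {}

    def forward(self, x, ctx):
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, training=ctx.train,
                            momentum=self.momentum, eps=self.eps,
                            mode=ctx.bn_stats if ctx.train else "batch",
                            stats_cache=self._stats_cache)


class Dropout(Module):
    def __init__(self, name, p=0.5):
        super().__init__(name)
        self.p = p

    def forward(self, x, ctx):
        if not ctx.train:
            return x
        return F.dropout(x, self.p, ctx.rng(self.name), training=True)


class ReLU(Module):
    def __init__(self, name="relu"):
        super().__init__(name)

    def forward(self, x, ctx):
        return F.relu(x)


class LeakyReLU(Module):
    def __init__(self, name="lrelu", alpha=0.2):
        super().__init__(name)
        self.alpha = alpha

    def forward(self, x, ctx):
        return F.leaky_relu(x, self.alpha)


class Sigmoid(Module):
    def __init__(self, name="sigmoid"):
        super().__init__(name)

    def forward(self, x, ctx):
        return F.sigmoid(x)


class Softmax(Module):
    def __init__(self, name="softmax"):
        super().__init__(name)

    def forward(self, x, ctx):
        return F.softmax(x)


class MaxPool2d(Module):
    def __init__(self, name="pool", k=2):
        super().__init__(name)
        self.k = k

    def forward(self, x, ctx):
        return F.max_pool2d(x, self.k)


class Flatten(Module):
    def __init__(self, name="flatten"):
        super().__init__(name)

    def forward(self, x, ctx):
        return F.flatten(x)
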