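"""Differentiable operations for the numpy autodiff engine.

Layout convention: spatial ops (convolutions, pooling, image batch norm) use
channels-last arrays ``(n, h, w, c)`` internally — im2col gathers are then
contiguous over the channel axis, which is what makes BLAS-backed
convolution viable on one CPU.  Public package interfaces are channels-first
``(n, c, h, w)``; :func:`nchw_to_nhwc` / :func:`nhwc_to_nchw` convert at
module boundaries.

Every backward rule here is exercised against a central finite-difference
oracle in ``tests/test_nn_gradients.py``.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

_EPS_LOG = 1e-8


# ---------------------------------------------------------------------------
# layout conversion
# ---------------------------------------------------------------------------

def nchw_to_nhwc(x: Tensor) -> Tensor:
    return Tensor(np.ascontiguousarray(x.data.transpose(0, 2, 3, 1)),
                  parents=(x,),
                  backward_fn=lambda g: (
                      np.ascontiguousarray(g.transpose(0, 3, 1, 2)),))


def nhwc_to_nchw(x: Tensor) -> Tensor:
    return Tensor(np.ascontiguousarray(x.data.transpose(0, 3, 1, 2)),
                  parents=(x,),
                  backward_fn=lambda g: (
                      np.ascontiguousarray(g.transpose(0, 2, 3, 1)),))


# ---------------------------------------------------------------------------
# im2col plumbing (channels-last)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(n, h, w, c) -> (n*ho*wo, kh*kw*c) patch matrix."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(
            f"kernel {kh}x{kw} (stride {stride}, pad {pad}) does not fit "
            f"input of spatial size {h}x{w}")
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, ho, wo, kh, kw, c),
        (s0, s1 * stride, s2 * stride, s1, s2, s3))
    return view.reshape(n * ho * wo, kh * kw * c), ho, wo


def _col2im(cols: np.ndarray, out_shape, kh, kw, stride, pad, ho, wo):
    """Adjoint of :func:`_im2col`: scatter-add patches into (n, h, w, c)."""
    n, h, w, c = out_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    gxp = np.zeros((n, hp, wp, c), dtype=np.float32)
    cols6 = cols.reshape(n, ho, wo, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            gxp[:, i:i + stride * ho:stride, j:j + stride * wo:stride, :] += \
                cols6[:, :, :, i, j, :]
    if pad:
        return np.ascontiguousarray(gxp[:, pad:pad + h, pad:pad + w, :])
    return gxp


# ---------------------------------------------------------------------------
# linear algebra layers
# ---------------------------------------------------------------------------

def linear(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """``y = x @ W + b`` with ``W`` of shape (in_features, out_features)."""
    y = x.data @ weight.data + bias.data

    def backward(g):
        return g @ weight.data.T, x.data.T @ g, g.sum(axis=0)

    return Tensor(y, parents=(x, weight, bias), backward_fn=backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
           pad: int = 0) -> Tensor:
    """2-D convolution on (n, h, w, c); ``weight`` shaped (kh, kw, c_in, c_out)."""
    kh, kw, ci, co = weight.shape
    n, h, w, c = x.shape
    if c != ci:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(-1, co)
    y = (cols @ wmat + bias.data).reshape(n, ho, wo, co)

    def backward(g):
        g2 = g.reshape(-1, co)
        gw = (cols.T @ g2).reshape(kh, kw, ci, co) if weight.requires_grad \
            else None
        gb = g2.sum(axis=0) if bias.requires_grad else None
        gx = _col2im(g2 @ wmat.T, x.shape, kh, kw, stride, pad, ho, wo) \
            if x.requires_grad else None
        return gx, gw, gb

    return Tensor(y, parents=(x, weight, bias), backward_fn=backward)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
                     pad: int = 0) -> Tensor:
    """Transposed convolution on (n, h, w, c); ``weight`` shaped
    (c_in, kh, kw, c_out).

    Output spatial size is ``(h - 1) * stride - 2 * pad + kh`` — the adjoint
    of :func:`conv2d` with the same geometry.
    """
    ci, kh, kw, co = weight.shape
    n, h, w, c = x.shape
    if c != ci:
        raise ValueError(
            f"conv_transpose2d: input has {c} channels, weight expects {ci}")
    ho_out = (h - 1) * stride - 2 * pad + kh
    wo_out = (w - 1) * stride - 2 * pad + kw
    x2 = x.data.reshape(-1, ci)
    wmat = weight.data.reshape(ci, -1)          # (ci, kh*kw*co)
    cols = x2 @ wmat
    y = _col2im(cols, (n, ho_out, wo_out, co), kh, kw, stride, pad, h, w)
    y += bias.data

    def backward(g):
        gcols, _, _ = _im2col(g, kh, kw, stride, pad)
        gx = (gcols @ wmat.T).reshape(n, h, w, ci) if x.requires_grad else None
        gw = (x2.T @ gcols).reshape(ci, kh, kw, co) if weight.requires_grad \
            else None
        gb = g.sum(axis=(0, 1, 2)) if bias.requires_grad else None
        return gx, gw, gb

    return Tensor(y, parents=(x, weight, bias), backward_fn=backward)


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping max pooling on (n, h, w, c).

    Specialised for ``k == 2`` (strided views, no patch copy); general ``k``
    falls back to a reshape-based reduction.
    """
    n, h, w, c = x.shape
    if h % k or w % k:
        raise ValueError(f"max_pool2d: size {h}x{w} not divisible by {k}")
    if k == 2:
        v = [x.data[:, i::2, j::2, :] for i in (0, 1) for j in (0, 1)]
        y = np.maximum(np.maximum(v[0], v[1]), np.maximum(v[2], v[3]))

        def backward(g):
            gx = np.zeros_like(x.data)
            taken = np.zeros(y.shape, dtype=bool)
            for (i, j), vij in zip(((0, 0), (0, 1), (1, 0), (1, 1)), v):
                hit = (vij == y) & ~taken
                taken |= hit
                gx[:, i::2, j::2, :] = np.where(hit, g, 0.0)
            return (gx,)

        return Tensor(y, parents=(x,), backward_fn=backward)

    h2, w2 = h // k, w // k
    patches = x.data.reshape(n, h2, k, w2, k, c).transpose(0, 1, 3, 5, 2, 4) \
        .reshape(n, h2, w2, c, k * k)
    idx = patches.argmax(axis=-1)
    y = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]

    def backward_general(g):
        gp = np.zeros_like(patches)
        np.put_along_axis(gp, idx[..., None], g[..., None], axis=-1)
        gx = gp.reshape(n, h2, w2, c, k, k).transpose(0, 1, 4, 2, 5, 3) \
            .reshape(n, h, w, c)
        return (np.ascontiguousarray(gx),)

    return Tensor(np.ascontiguousarray(y), parents=(x,),
                  backward_fn=backward_general)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    return Tensor(y, parents=(x,),
                  backward_fn=lambda g: (g * (y > 0),))


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    mask = x.data > 0
    return Tensor(np.where(mask, x.data, alpha * x.data), parents=(x,),
                  backward_fn=lambda g: (np.where(mask, g, alpha * g),))


def sigmoid(x: Tensor) -> Tensor:
    z = x.data
    s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))
    s = s.astype(np.float32)
    return Tensor(s, parents=(x,), backward_fn=lambda g: (g * s * (1.0 - s),))


def softmax(x: Tensor) -> Tensor:
    """Row-wise softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        return (p * (g - (g * p).sum(axis=-1, keepdims=True)),)

    return Tensor(p, parents=(x,), backward_fn=backward)


# ---------------------------------------------------------------------------
# normalisation / regularisation
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5, mode: str = "batch",
               stats_cache: dict | None = None) -> Tensor:
    """Batch normalisation over the *last* axis of any-rank input.

    Covers both (n, f) feature matrices and (n, h, w, c) image stacks.
    ``running_mean``/``running_var`` are plain arrays owned by the layer,
    updated in place when training with ``mode="batch"`` (unbiased running
    variance).

    ``mode="reuse"`` (training only) normalises with the statistics stored
    in ``stats_cache`` by the preceding ``mode="batch"`` call, treated as
    constants in the backward pass, and leaves the running buffers
    untouched.  This anchors a second (e.g. target-domain) half-step to the
    first half's normalisation scale.
    """
    xd = x.data
    c = xd.shape[-1]
    x2 = xd.reshape(-1, c)
    m = x2.shape[0]

    if training and mode in ("batch", "batch_nobuf"):
        s1 = x2.sum(axis=0)
        s2 = np.einsum("nc,nc->c", x2, x2)
        mu = s1 / m
        var = np.maximum(s2 / m - mu * mu, 0.0)
        inv = 1.0 / np.sqrt(var + eps)
        if mode == "batch":
            running_mean *= (1.0 - momentum)
            running_mean += momentum * mu
            running_var *= (1.0 - momentum)
            running_var += momentum * var * (m / max(m - 1, 1))
        if stats_cache is not None:
            stats_cache["mu"], stats_cache["inv"] = mu, inv
    elif training and mode == "reuse":
        if not stats_cache or "mu" not in stats_cache:
            raise RuntimeError("batch_norm mode='reuse' requires a preceding "
                               "mode='batch' call on the same layer")
        mu, inv = stats_cache["mu"], stats_cache["inv"]
    elif training:
        raise ValueError(f"unknown batch_norm mode '{mode}'")
    else:
        mu = running_mean
        inv = 1.0 / np.sqrt(running_var + eps)

    a = (gamma.data * inv).astype(np.float32)
    b = (beta.data - mu * a).astype(np.float32)
    y = xd * a + b  # single fused pass

    if training and mode in ("batch", "batch_nobuf"):
        def backward(g):
            g2 = g.reshape(-1, c)
            sum_g = g2.sum(axis=0)
            sum_gx = np.einsum("nc,nc->c", g2, x2)
            ggam = (sum_gx - mu * sum_g) * inv
            gbet = sum_g
            # gx = a*(g - mean(g) - xhat*mean(g*xhat)) expressed as
            #      alpha*g + beta1*x + beta0 with per-channel coefficients
            mean_g = sum_g / m
            mean_gxhat = (sum_gx / m - mu * mean_g) * inv
            beta1 = -a * inv * mean_gxhat
            beta0 = -a * mean_g - beta1 * mu
            gx = g * a
            gx += xd * beta1
            gx += beta0
            return gx.astype(np.float32, copy=False), ggam, gbet
    else:
        def backward(g):
            g2 = g.reshape(-1, c)
            sum_g = g2.sum(axis=0)
            sum_gx = np.einsum("nc,nc->c", g2, x2)
            ggam = (sum_gx - mu * sum_g) * inv
            return (g * a).astype(np.float32, copy=False), ggam, sum_g

    return Tensor(y, parents=(x, gamma, beta), backward_fn=backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; the mask is drawn from the caller-supplied ``rng``."""
    if not training or p == 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float32) / (1.0 - p)
    return Tensor(x.data * keep, parents=(x,),
                  backward_fn=lambda g: (g * keep,))


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(x: Tensor, shape) -> Tensor:
    old = x.shape
    return Tensor(x.data.reshape(shape), parents=(x,),
                  backward_fn=lambda g: (g.reshape(old),))


def flatten(x: Tensor) -> Tensor:
    return reshape(x, (x.shape[0], -1))


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.ascontiguousarray(p)
                     for p in np.split(g, splits, axis=axis))

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors),
                  backward_fn=backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"add: shape mismatch {a.shape} vs {b.shape}")
    return Tensor(a.data + b.data, parents=(a, b),
                  backward_fn=lambda g: (g, g))


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup with scatter-add gradient into the table."""
    idx = np.asarray(indices, dtype=np.int64)
    out = table.data[idx]

    def backward(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, idx, g)
        return (gt,)

    return Tensor(out, parents=(table,), backward_fn=backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def cross_entropy_from_probs(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood from an (n, k) probability matrix."""
    y = np.asarray(labels, dtype=np.int64)
    if y.ndim != 1 or y.shape[0] != probs.shape[0]:
        raise ValueError("labels must be a 1-D array matching the batch size")
    n = probs.shape[0]
    picked = probs.data[np.arange(n), y]
    loss = -np.log(np.maximum(picked, _EPS_LOG)).mean()

    def backward(g):
        gp = np.zeros_like(probs.data)
        gp[np.arange(n), y] = -g / (n * np.maximum(picked, _EPS_LOG))
        return (gp,)

    return Tensor(np.float32(loss), parents=(probs,), backward_fn=backward)


def clip01_straight_through(x: Tensor) -> Tensor:
    """Clamp to [0, 1] forward; identity backward (straight-through).

    Used on generator output so the discriminator always sees in-gamut
    pixels while saturated pixels keep receiving corrective gradient.
    """
    return Tensor(np.clip(x.data, 0.0, 1.0), parents=(x,),
                  backward_fn=lambda g: (g,))


def binary_cross_entropy(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE between probabilities in (0, 1) and 0/1 targets."""
    t = np.asarray(targets, dtype=np.float32).reshape(probs.shape)
    # 1e-6 is the smallest float32-representable margin below 1.0
    p = np.clip(probs.data, 1e-6, 1.0 - 1e-6)
    loss = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()
    n = probs.data.size

    def backward(g):
        return ((g / n) * (-(t / p) + (1.0 - t) / (1.0 - p)),)

    return Tensor(np.float32(loss), parents=(probs,), backward_fn=backward)


# ---------------------------------------------------------------------------
# gradient reversal
# ---------------------------------------------------------------------------

def gradient_reversal(x: Tensor, coeff) -> Tensor:
    """Identity forward; backward multiplies the gradient by ``-coeff.value``.

    ``coeff`` is any object with a ``value`` attribute read at backward time,
    so a schedule may mutate it between steps without rebuilding the graph.
    """
    return Tensor(x.data, parents=(x,),
                  backward_fn=lambda g: ((-coeff.value) * g,))
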