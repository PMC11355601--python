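"""Finite-difference verification of every backward rule in the autodiff
engine.

Each check projects the op's output onto a fixed random vector to obtain a
scalar, then compares analytic gradients against central finite differences
of that scalar.  Step sizes are chosen for float32 forward arithmetic
(truncation ~h^2, rounding ~eps/h)."""

import numpy as np
import pytest

from dermadapt.nn import Tensor
from dermadapt.nn import functional as F

RNG = np.random.default_rng(20240814)
H = 0.05
TOL = dict(rtol=2e-2, atol=2e-3)


def fd_grad(f, x, h=H):
    """Central finite differences of scalar f at array x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + h
        fp = f(x)
        flat[i] = orig - h
        fm = f(x)
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * h)
    return g


def check_input_grad(build, x0):
    """build(Tensor) -> scalar Tensor; verifies gradient w.r.t. the input."""
    xt = Tensor(x0, requires_grad=True)
    loss = build(xt)
    loss.backward()
    num = fd_grad(lambda a: float(build(Tensor(a)).data), x0.copy())
    np.testing.assert_allclose(xt.grad, num, **TOL)


def scalar_proj(w):
    """Returns a closure turning an op output into a scalar via fixed w."""
    def inner(t):
        out = Tensor((t.data.reshape(-1) * w).sum(), parents=(t,),
                     backward_fn=lambda g: ((g * w).reshape(t.shape),))
        return out
    return inner


def test_linear_gradients():
    x0 = RNG.normal(size=(5, 4)).astype(np.float32)
    W = Tensor(RNG.normal(size=(4, 3)).astype(np.float32), requires_grad=True)
    b = Tensor(RNG.normal(size=3).astype(np.float32), requires_grad=True)
    w = RNG.normal(size=15).astype(np.float32)
    proj = scalar_proj(w)
    check_input_grad(lambda t: proj(F.linear(t, W, b)), x0)
    # weight gradient
    xt = Tensor(x0)
    loss = proj(F.linear(xt, W, b))
    W.grad = b.grad = None
    loss.backward()
    num = fd_grad(lambda a: float((np.asarray(x0 @ a + b.data, dtype=np.float32)
                                   .reshape(-1) * w).sum()), W.data.copy())
    np.testing.assert_allclose(W.grad, num, **TOL)


@pytest.mark.parametrize("stride,pad", [(1, 1), (2, 1), (1, 0)])
def test_conv2d_gradients(stride, pad):
    x0 = RNG.normal(size=(2, 6, 6, 3)).astype(np.float32)
    W = Tensor(RNG.normal(size=(3, 3, 3, 4)).astype(np.float32),
               requires_grad=True)
    b = Tensor(RNG.normal(size=4).astype(np.float32), requires_grad=True)
    out = F.conv2d(Tensor(x0), W, b, stride, pad)
    w = RNG.normal(size=out.data.size).astype(np.float32)
    proj = scalar_proj(w)
    check_input_grad(lambda t: proj(F.conv2d(t, W, b, stride, pad)), x0)
    W.grad = b.grad = None
    loss = proj(F.conv2d(Tensor(x0), W, b, stride, pad))
    loss.backward()
    num_w = fd_grad(
        lambda a: float(proj(F.conv2d(Tensor(x0), Tensor(a), b, stride,
                                      pad)).data), W.data.copy())
    np.testing.assert_allclose(W.grad, num_w, **TOL)
    num_b = fd_grad(
        lambda a: float(proj(F.conv2d(Tensor(x0), W, Tensor(a), stride,
                                      pad)).data), b.data.copy())
    np.testing.assert_allclose(b.grad, num_b, **TOL)


@pytest.mark.parametrize("stride,pad", [(2, 1), (1, 0)])
def test_conv_transpose2d_gradients(stride, pad):
    x0 = RNG.normal(size=(2, 4, 4, 3)).astype(np.float32)
    W = Tensor(RNG.normal(size=(3, 4, 4, 2)).astype(np.float32),
               requires_grad=True)
    b = Tensor(RNG.normal(size=2).astype(np.float32), requires_grad=True)
    out = F.conv_transpose2d(Tensor(x0), W, b, stride, pad)
    w = RNG.normal(size=out.data.size).astype(np.float32)
    proj = scalar_proj(w)
    check_input_grad(lambda t: proj(F.conv_transpose2d(t, W, b, stride, pad)),
                     x0)
    W.grad = None
    loss = proj(F.conv_transpose2d(Tensor(x0), W, b, stride, pad))
    loss.backward()
    num_w = fd_grad(
        lambda a: float(proj(F.conv_transpose2d(Tensor(x0), Tensor(a), b,
                                                stride, pad)).data),
        W.data.copy())
    np.testing.assert_allclose(W.grad, num_w, **TOL)


def test_conv_transpose_matches_adjoint_shape():
    x = Tensor(RNG.normal(size=(1, 5, 5, 3)).astype(np.float32))
    W = Tensor(RNG.normal(size=(3, 4, 4, 4)).astype(np.float32))
    b = Tensor(np.zeros(4, np.float32))
    y = F.conv_transpose2d(x, W, b, stride=2, pad=1)
    assert y.shape == (1, 10, 10, 4)


def test_max_pool_gradients():
    # well-separated values: the argmax is stable under the FD perturbation
    x0 = (RNG.permutation(np.arange(64)).reshape(2, 2, 4, 4) * 0.5
          ).astype(np.float32)
    out = F.max_pool2d(Tensor(x0), 2)
    w = RNG.normal(size=out.data.size).astype(np.float32)
    proj = scalar_proj(w)
    check_input_grad(lambda t: proj(F.max_pool2d(t, 2)), x0)


@pytest.mark.parametrize("opname", ["relu", "leaky_relu", "sigmoid", "softmax"])
def test_activation_gradients(opname):
    op = getattr(F, opname)
    x0 = RNG.normal(size=(4, 5)).astype(np.float32)
    x0 += np.sign(x0) * 0.2  # keep inputs away from the kink at 0
    out = op(Tensor(x0))
    w = RNG.normal(size=out.data.size).astype(np.float32)
    proj = scalar_proj(w)
    check_input_grad(lambda t: proj(op(t)), x0)


@pytest.mark.parametrize("training", [True, False])
def test_batch_norm_gradients(training):
    x0 = RNG.normal(size=(6, 3)).astype(np.float32)
    gamma = Tensor(RNG.normal(1.0, 0.1, size=3).astype(np.float32),
                   requires_grad=True)
    beta = Tensor(RNG.normal(size=3).astype(np.float32), requires_grad=True)
    rm = RNG.normal(size=3).astype(np.float32)
    rv = np.abs(RNG.normal(1.0, 0.1, size=3)).astype(np.float32)
    w = RNG.normal(size=18).astype(np.float32)
    proj = scalar_proj(w)

    def build(t):
        return proj(F.batch_norm(t, gamma, beta, rm.copy(), rv.copy(),
                                 training=training))

    check_input_grad(build, x0)
    gamma.grad = beta.grad = None
    loss = build(Tensor(x0))
    loss.backward()
    num_g = fd_grad(
        lambda a: float(proj(F.batch_norm(Tensor(x0), Tensor(a), beta,
                                          rm.copy(), rv.copy(),
                                          training=training)).data),
        gamma.data.copy())
    np.testing.assert_allclose(gamma.grad, num_g, **TOL)


def test_batch_norm_4d_gradients():
    x0 = RNG.normal(size=(3, 4, 4, 2)).astype(np.float32)
    gamma = Tensor(np.ones(2, np.float32), requires_grad=True)
    beta = Tensor(np.zeros(2, np.float32), requires_grad=True)
    rm, rv = np.zeros(2, np.float32), np.ones(2, np.float32)
    w = RNG.normal(size=x0.size).astype(np.float32)
    proj = scalar_proj(w)
    check_input_grad(
        lambda t: proj(F.batch_norm(t, gamma, beta, rm.copy(), rv.copy(),
                                    training=True)), x0)


def test_cross_entropy_from_probs_gradient():
    logits = RNG.normal(size=(5, 2)).astype(np.float32)
    labels = np.array([0, 1, 1, 0, 1])

    def build(t):
        return F.cross_entropy_from_probs(F.softmax(t), labels)

    check_input_grad(build, logits)


def test_binary_cross_entropy_gradient():
    logits = RNG.normal(size=(6, 1)).astype(np.float32)
    targets = np.array([1, 0, 1, 1, 0, 0], np.float32).reshape(6, 1)

    def build(t):
        return F.binary_cross_entropy(F.sigmoid(t), targets)

    check_input_grad(build, logits)


def test_concat_and_reshape_gradients():
    a0 = RNG.normal(size=(3, 2)).astype(np.float32)
    b = Tensor(RNG.normal(size=(3, 4)).astype(np.float32))
    proj18 = scalar_proj(RNG.normal(size=18).astype(np.float32))
    proj6 = scalar_proj(RNG.normal(size=6).astype(np.float32))
    check_input_grad(lambda t: proj18(F.concat([t, b], axis=1)), a0)
    check_input_grad(lambda t: proj6(F.reshape(t, (2, 3))), a0)


def test_embedding_gradient():
    table = Tensor(RNG.normal(size=(2, 4)).astype(np.float32),
                   requires_grad=True)
    idx = np.array([0, 1, 1, 0, 1])
    w = RNG.normal(size=20).astype(np.float32)
    proj = scalar_proj(w)
    loss = proj(F.embedding(table, idx))
    loss.backward()
    num = fd_grad(lambda a: float(proj(F.embedding(Tensor(a), idx)).data),
                  table.data.copy())
    np.testing.assert_allclose(table.grad, num, **TOL)


def test_gradient_accumulates_across_two_uses():
    """A tensor consumed by two branches receives the sum of both gradients."""
    x0 = RNG.normal(size=(3, 3)).astype(np.float32)
    w = RNG.normal(size=9).astype(np.float32)
    proj = scalar_proj(w)

    def build(t):
        return proj(F.add(F.relu(t), F.leaky_relu(t, 0.3)))

    check_input_grad(build, x0 + 0.2)
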