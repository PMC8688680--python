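"""Gradient and shape checks for the NumPy layer stack.

Finite differences are run in float64 (layers preserve the input dtype)
against the analytic backward passes; the full network is checked
end-to-end through the loss.
"""

import numpy as np
import pytest

from dexaseg.dataio import one_hot
from dexaseg.loss import gdl_value_and_grad
from dexaseg.network import NetworkSpec, SegNet
from dexaseg.nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d, ReLU


def fd_param_grad(loss_fn, param, j, eps=1e-6):
    flat = param.data.ravel()
    old = flat[j]
    flat[j] = old + eps
    lp = loss_fn()
    flat[j] = old - eps
    lm = loss_fn()
    flat[j] = old
    return (lp - lm) / (2 * eps)


def layer_loss(layer, x, w=None):
    """Scalar probe sum(w * forward(x)) so dL/dy = w."""
    y = layer.forward(x, train=True)
    return float((y * w).sum())


@pytest.mark.parametrize("kernel", [1, 3])
def test_conv2d_gradients(kernel, rng):
    layer = Conv2d(3, 4, kernel, rng)
    for p in layer.parameters():
        p.astype(np.float64)
    x = rng.standard_normal((2, 3, 6, 6))
    w = rng.standard_normal((2, 4, 6, 6))
    y = layer.forward(x, train=True)
    assert y.shape == (2, 4, 6, 6)
    layer.zero_grad()
    dx = layer.backward(w)
    # input gradient
    j = 17
    eps = 1e-6
    xf = x.ravel()
    old = xf[j]
    xf[j] = old + eps
    lp = layer_loss(layer, x, w)
    xf[j] = old - eps
    lm = layer_loss(layer, x, w)
    xf[j] = old
    assert dx.ravel()[j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-6)
    # parameter gradients
    layer.zero_grad()
    layer.forward(x, train=True)
    layer.backward(w)
    for param in layer.parameters():
        j = 1 % param.size
        num = fd_param_grad(lambda: layer_loss(layer, x, w), param, j)
        assert param.grad.ravel()[j] == pytest.approx(num, rel=1e-6, abs=1e-9)


def test_transposed_conv_upsamples_and_grads(rng):
    layer = ConvTranspose2d(3, 2, rng)
    for p in layer.parameters():
        p.astype(np.float64)
    x = rng.standard_normal((2, 3, 4, 4))
    w = rng.standard_normal((2, 2, 8, 8))
    y = layer.forward(x, train=True)
    assert y.shape == (2, 2, 8, 8)
    layer.zero_grad()
    layer.backward(w)
    for param in layer.parameters():
        num = fd_param_grad(lambda: layer_loss(layer, x, w), param, 0)
        assert param.grad.ravel()[0] == pytest.approx(num, rel=1e-6, abs=1e-9)


def test_batchnorm_train_normalizes_and_grads(rng):
    layer = BatchNorm2d(3)
    for p in layer.parameters():
        p.astype(np.float64)
    x = rng.standard_normal((4, 3, 5, 5)) * 3 + 1
    y = layer.forward(x, train=True)
    assert np.allclose(y.mean(axis=(0, 2, 3)), 0, atol=1e-10)
    assert np.allclose(y.std(axis=(0, 2, 3)), 1, atol=1e-3)
    w = rng.standard_normal(y.shape)
    layer.zero_grad()
    dx = layer.backward(w)
    j = 31
    eps = 1e-6
    xf = x.ravel()
    old = xf[j]
    xf[j] = old + eps
    lp = layer_loss(layer, x, w)
    xf[j] = old - eps
    lm = layer_loss(layer, x, w)
    xf[j] = old
    assert dx.ravel()[j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-5)


def test_batchnorm_eval_uses_running_stats(rng):
    layer = BatchNorm2d(2)
    x = rng.standard_normal((4, 2, 3, 3)).astype(np.float32)
    y0 = layer.forward(x, train=False)  # fresh stats: mean 0, var 1 -> identity
    assert np.allclose(y0, x, atol=1e-5)
    for _ in range(200):
        layer.forward(x, train=True)
    y1 = layer.forward(x, train=False)
    assert np.allclose(y1.mean(axis=(0, 2, 3)), 0, atol=1e-2)


def test_maxpool_selects_max_and_routes_gradient():
    x = np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4)
    pool = MaxPool2d()
    y = pool.forward(x, train=True)
    assert y.ravel().tolist() == [5.0, 7.0, 13.0, 15.0]
    dx = pool.backward(np.ones_like(y))
    assert dx.sum() == 4
    assert dx[0, 0, 1, 1] == 1 and dx[0, 0, 0, 0] == 0


def test_maxpool_odd_input_rejected():
    with pytest.raises(ValueError, match="even"):
        MaxPool2d().forward(np.zeros((1, 1, 5, 4)))


def test_relu_masks_gradient(rng):
    x = rng.standard_normal((2, 2, 3, 3))
    r = ReLU()
    y = r.forward(x, train=True)
    dx = r.backward(np.ones_like(y))
    assert np.array_equal(dx, (x > 0).astype(float))


def test_full_network_gradient_matches_finite_difference(rng):
    model = SegNet(NetworkSpec(base_channels=2), seed=3)
    for p in model.parameters():
        p.astype(np.float64)
    x = rng.random((2, 1, 16, 16))
    labels = rng.integers(0, 3, (2, 16, 16))
    truth = np.stack([one_hot(l) for l in labels]).astype(np.float64)

    def loss_fn():
        return gdl_value_and_grad(model.forward(x, train=True), truth)[0]

    probs = model.forward(x, train=True)
    _, dprobs = gdl_value_and_grad(probs, truth)
    model.zero_grad()
    model.backward(dprobs)
    params = model.parameters()
    picker = np.random.default_rng(0)
    for pi in picker.choice(len(params), 10, replace=False):
        param = params[pi]
        j = int(picker.integers(param.size))
        num = fd_param_grad(loss_fn, param, j)
        ana = param.grad.ravel()[j]
        assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), param.name


def test_adam_reduces_quadratic_loss():
    p = __import__("dexaseg.nn", fromlist=["Parameter"]).Parameter(np.array([5.0, -3.0]))
    opt = Adam([p])
    for _ in range(2000):
        p.grad[...] = 2 * p.data  # d/dx of x^2
        opt.step(0.01)
        p.grad[...] = 0
    assert np.abs(p.data).max() < 1e-3
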