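"""Finite-difference gradient checks for the numpy autodiff engine.

Every layer family used by the networks is checked against central
differences on tiny inputs; this is the ground truth the training loop
stands on.
"""

import numpy as np
import pytest

from aneuseg import nn
from aneuseg.nn import Tensor, functional as F


def numerical_grad(fn, arr, eps=1e-2):
    # float32 forward evaluations: central differences need a coarse step
    g = np.zeros_like(arr, dtype=np.float64)
    flat = arr.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn()
        flat[i] = orig - eps
        lo = fn()
        flat[i] = orig
        g.reshape(-1)[i] = (hi - lo) / (2 * eps)
    return g


def check_param_grad(build_loss, param, tol=2e-2):
    """Compare backprop gradient of `param` with central differences."""
    loss = build_loss()
    loss.backward()
    analytic = param.grad.copy()
    numeric = numerical_grad(lambda: build_loss().item(), param.data)
    scale = max(np.abs(numeric).max(), 1e-6)
    assert np.abs(analytic - numeric).max() / scale < tol


@pytest.mark.parametrize("stride,k", [(1, 3), (2, 3), (1, 1)])
def test_conv3d_weight_and_input_gradients(stride, k):
    rng = np.random.default_rng(0)
    x = Tensor(rng.normal(size=(2, 4, 4, 4, 3)), requires_grad=True)
    w = Tensor(rng.normal(size=(2, 3, k, k, k)), requires_grad=True)
    b = Tensor(rng.normal(size=2), requires_grad=True)

    def loss():
        x.grad = w.grad = b.grad = None
        out = F.conv3d(x, w, b, stride=stride)
        return (out * out).sum()

    for p in (w, x, b):
        check_param_grad(loss, p)


def test_conv3d_matches_brute_force_correlation():
    from scipy import ndimage
    rng = np.random.default_rng(1)
    x = rng.normal(size=(1, 6, 7, 8, 1)).astype(np.float32)
    w = rng.normal(size=(1, 1, 3, 3, 3)).astype(np.float32)
    out = F.conv3d(Tensor(x), Tensor(w), None, 1).data[0, ..., 0]
    ref = ndimage.correlate(x[0, ..., 0].astype(np.float64), w[0, 0], mode="constant")
    assert np.abs(out - ref).max() < 1e-5


def test_upsample_and_reductions_gradients():
    rng = np.random.default_rng(2)
    x = Tensor(rng.normal(size=(1, 2, 2, 2, 3)), requires_grad=True)

    def loss():
        x.grad = None
        up = F.upsample_nearest(x, 2)
        return (up * up).mean() + x.sum(axis=(1, 2, 3), keepdims=True).sum()

    check_param_grad(loss, x)


def test_softmax_sigmoid_norm_gradients():
    rng = np.random.default_rng(3)
    x = Tensor(rng.normal(size=(1, 2, 2, 2, 4)), requires_grad=True)
    norm = nn.InstanceNorm3d(4)

    def loss():
        x.grad = None
        for p in norm.parameters():
            p.grad = None
        h = norm(x).softmax(axis=-1).sigmoid()
        return (h * h).sum()

    check_param_grad(loss, x)
    check_param_grad(loss, norm.gamma)


def test_se_block_gradients():
    rng = np.random.default_rng(4)
    se = nn.SEBlock(4, reduction=2, rng=rng)
    x = Tensor(rng.normal(size=(1, 2, 2, 2, 4)), requires_grad=True)

    def loss():
        x.grad = None
        for p in se.parameters():
            p.grad = None
        return (se(x) ** 2.0).sum()

    check_param_grad(loss, x)
    check_param_grad(loss, se.fc1.weight)


def test_getitem_concat_transpose_gradients():
    rng = np.random.default_rng(5)
    a = Tensor(rng.normal(size=(2, 3, 2, 2, 2)), requires_grad=True)

    def loss():
        a.grad = None
        t = a.transpose(0, 2, 3, 4, 1)
        c = nn.concat([t, t * 2.0], axis=-1)
        return (c[:, 1] ** 2.0).sum()

    check_param_grad(loss, a)


def test_dropout_eval_mode_is_identity():
    x = Tensor(np.ones((1, 2, 2, 2, 2)))
    drop = nn.Dropout(0.5, seed=0)
    drop.eval()
    assert np.array_equal(drop(x).data, x.data)


def test_optimizer_step_reduces_quadratic_loss():
    for opt_cls in (nn.Adam, nn.RMSProp):
        w = Tensor(np.array([3.0, -2.0]), requires_grad=True)
        opt = opt_cls([w], lr=0.1)
        first = None
        for _ in range(50):
            opt.zero_grad()
            loss = (w * w).sum()
            loss.backward()
            if first is None:
                first = loss.item()
            opt.step()
        assert (w.data ** 2).sum() < first
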