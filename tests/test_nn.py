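"""Gradient and contract checks for the autodiff core.

Every layer's analytic gradient is compared against central finite
differences; optimiser and scheduler behaviour is checked against the
closed-form update rules.
"""

import numpy as np
import pytest

from wheatcount import nn

from conftest import numerical_gradient


def _check_grads(make_loss, tensors, tol=2e-2):
    loss = make_loss()
    loss.backward()
    for t in tensors:
        analytic = t.grad
        assert analytic is not None
        numeric = numerical_gradient(lambda: float(make_loss().data), t.data)
        scale = np.abs(numeric).max() + 1e-8
        assert np.abs(analytic - numeric).max() / scale < tol
        t.grad = None


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestGradients:
    def test_conv2d_3x3(self, rng):
        x = nn.Parameter(rng.standard_normal((2, 3, 6, 6)))
        conv = nn.Conv2d(3, 4, 3, rng)
        _check_grads(lambda: conv(x).sum(), [x, conv.weight, conv.bias])

    def test_conv2d_7x7(self, rng):
        x = nn.Parameter(rng.standard_normal((1, 2, 8, 8)))
        conv = nn.Conv2d(2, 1, 7, rng)
        _check_grads(lambda: conv(x).sum(), [x, conv.weight, conv.bias])

    def test_maxpool(self, rng):
        x = nn.Parameter(rng.standard_normal((2, 3, 4, 4)))
        pool = nn.MaxPool2x2()
        _check_grads(lambda: pool(x).sum(), [x])

    def test_layernorm(self, rng):
        x = nn.Parameter(rng.standard_normal((3, 5, 8)))
        ln = nn.LayerNorm(8)
        w = nn.Tensor(rng.standard_normal((3, 5, 8)))  # break symmetry
        _check_grads(lambda: (ln(x) * w).sum(), [x, ln.gamma, ln.beta])

    def test_linear_relu_sigmoid(self, rng):
        x = nn.Parameter(rng.standard_normal((4, 6)))
        lin = nn.Linear(6, 3, rng)
        _check_grads(lambda: nn.sigmoid(nn.relu(lin(x))).sum(),
                     [x, lin.weight, lin.bias])

    @pytest.mark.parametrize("pool", [nn.global_max_pool, nn.global_avg_pool,
                                      nn.channel_max_pool, nn.channel_avg_pool])
    def test_pooling_ops(self, rng, pool):
        x = nn.Parameter(rng.standard_normal((2, 4, 5, 5)))
        w = nn.Tensor(rng.standard_normal(pool(nn.Tensor(x.data)).shape))
        _check_grads(lambda: (pool(x) * w).sum(), [x])

    def test_concat_abs_mean(self, rng):
        a = nn.Parameter(rng.standard_normal((3, 4)))
        b = nn.Parameter(rng.standard_normal((3, 2)))
        _check_grads(lambda: nn.concat([a, b], axis=1).abs().mean(), [a, b])

    def test_batched_matmul(self, rng):
        a = nn.Parameter(rng.standard_normal((2, 3, 4)))
        b = nn.Parameter(rng.standard_normal((4, 5)))
        _check_grads(lambda: (a @ b).sum(), [a, b])

    def test_broadcast_add_mul(self, rng):
        a = nn.Parameter(rng.standard_normal((3, 4)))
        b = nn.Parameter(rng.standard_normal(4))
        _check_grads(lambda: ((a + b) * b).sum(), [a, b])

    def test_reused_tensor_accumulates(self, rng):
        # y = x*x + x: dy/dx = 2x + 1
        x = nn.Parameter(rng.standard_normal(5))
        (x * x + x).sum().backward()
        assert np.allclose(x.grad, 2 * x.data + 1, atol=1e-5)


def test_conv_compiled_and_column_paths_agree(rng):
    """The compiled large-grid convolution must match the column-matrix path
    bit-for-bit forward and to float32 rounding in the gradients."""
    from wheatcount import _convkernels as ck
    if not ck.HAVE_NUMBA:
        x_small = nn.Parameter(rng.standard_normal((1, 2, 40, 40)))
        conv = nn.Conv2d(2, 3, 3, rng)
        conv(x_small).sum().backward()  # column path still works
        return
    x = nn.Parameter(rng.standard_normal((2, 3, 40, 40)))
    conv = nn.Conv2d(3, 5, 3, rng)
    out_fast = conv(x)
    out_fast.sum().backward()
    fast = (out_fast.data, x.grad, conv.weight.grad, conv.bias.grad)
    x.grad = conv.weight.grad = conv.bias.grad = None
    saved = ck.MIN_GRID
    try:
        ck.MIN_GRID = 10 ** 9  # force the column path
        out_ref = conv(x)
        out_ref.sum().backward()
    finally:
        ck.MIN_GRID = saved
    ref = (out_ref.data, x.grad, conv.weight.grad, conv.bias.grad)
    assert np.array_equal(fast[0], ref[0])
    for f, r in zip(fast[1:], ref[1:]):
        assert np.allclose(f, r, rtol=1e-4, atol=1e-4 * np.abs(r).max())


class TestOptim:
    def test_sgd_matches_momentum_recurrence(self):
        p = nn.Parameter(np.array([1.0, -2.0]))
        opt = nn.SGD([p], lr=0.1, momentum=0.9)
        v = np.zeros(2)
        w = p.data.copy()
        for step in range(4):
            p.grad = np.array([0.5, -1.0], dtype=np.float32) * (step + 1)
            v = 0.9 * v + p.grad
            w = w - 0.1 * v
            opt.step()
            assert np.allclose(p.data, w, atol=1e-6)

    def test_multistep_schedule(self):
        p = nn.Parameter(np.zeros(1))
        opt = nn.SGD([p], lr=1e-4, momentum=0.0)
        sched = nn.MultiStepLR(opt, milestones=[2], gamma=0.1)
        lrs = []
        for _ in range(3):
            lrs.append(opt.lr)
            sched.step()
        # lr at epoch 3 (after milestone 2) is 0.1x the initial lr
        assert lrs == pytest.approx([1e-4, 1e-4, 1e-5])

    def test_milestones_must_increase(self):
        opt = nn.SGD([nn.Parameter(np.zeros(1))], lr=0.1)
        with pytest.raises(ValueError):
            nn.MultiStepLR(opt, milestones=[5, 2])

    def test_no_grad_blocks_tape(self):
        x = nn.Parameter(np.ones(3))
        with nn.no_grad():
            y = (x * 2.0).sum()
        assert not y.requires_grad

    def test_dropout_eval_identity_train_scales(self, rng):
        drop = nn.Dropout(0.5, rng)
        x = nn.Tensor(np.ones((200, 50)))
        drop.train(False)
        assert np.array_equal(drop(x).data, x.data)
        drop.train(True)
        out = drop(x).data
        assert set(np.unique(out)) == {0.0, 2.0}  # inverted dropout scaling
        assert abs(out.mean() - 1.0) < 0.05
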