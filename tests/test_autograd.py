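"""Finite-difference validation of the reverse-mode engine and nn ops."""

import numpy as np
import pytest
from scipy import ndimage

from prostreg._autograd import Tensor, concat, no_grad, stack
from prostreg.nn import Adam, LSTM, Linear, conv3d, max_pool3d, upsample_trilinear_2x

from conftest import numeric_grad


def check(f, args, tol=1e-6):
    """Compare autograd gradients of sum(f(*args)) against central differences."""
    ts = [Tensor(a.astype(np.float64), requires_grad=True) for a in args]
    out = f(*ts)
    (out.sum() if out.size > 1 else out).backward()
    for j, a in enumerate(args):
        def scalar(mod):
            vals = [x.copy() for x in args]
            vals[j] = mod
            o = f(*[Tensor(v) for v in vals])
            return float(o.data.sum())

        num = numeric_grad(scalar, a.astype(np.float64))
        np.testing.assert_allclose(ts[j].grad, num, rtol=1e-4, atol=tol)


class TestElementwise:
    def test_add_mul_broadcast(self, rng):
        a = rng.standard_normal((3, 4))
        b = rng.standard_normal((1, 4))
        check(lambda x, y: x * y + x, [a, b])

    def test_pow_div(self, rng):
        a = rng.uniform(0.5, 2.0, (3, 3))
        b = rng.uniform(0.5, 2.0, (3, 3))
        check(lambda x, y: x / y + x ** 3, [a, b])

    def test_activations(self, rng):
        a = rng.standard_normal((4, 5))
        check(lambda x: x.sigmoid(), [a])
        check(lambda x: x.tanh(), [a])
        check(lambda x: (x + 5.0).log(), [a])
        check(lambda x: x.exp(), [a])
        check(lambda x: x.leaky_relu(0.2), [a + 0.05])  # avoid kink
        check(lambda x: x.relu(), [a + 0.05])

    def test_softmax_rows_sum_to_one(self, rng):
        x = Tensor(rng.standard_normal((5, 7)))
        s = x.softmax(axis=1)
        np.testing.assert_allclose(s.data.sum(axis=1), 1.0, atol=1e-7)
        a = rng.standard_normal((3, 4))
        check(lambda x: x.softmax(axis=1) * Tensor(np.arange(4.0)), [a])


class TestShapeOps:
    def test_matmul(self, rng):
        a = rng.standard_normal((3, 4))
        b = rng.standard_normal((4, 2))
        check(lambda x, y: x @ y, [a, b])

    def test_batched_matmul(self, rng):
        a = rng.standard_normal((2, 3, 4))
        b = rng.standard_normal((2, 4, 2))
        check(lambda x, y: x @ y, [a, b])

    def test_reductions(self, rng):
        a = rng.standard_normal((3, 4, 2))
        check(lambda x: x.sum(axis=(0, 2)), [a])
        check(lambda x: x.mean(axis=1, keepdims=True), [a])
        check(lambda x: x.max(axis=1), [a])

    def test_reshape_transpose_getitem(self, rng):
        a = rng.standard_normal((4, 6))
        check(lambda x: x.reshape(2, 12), [a])
        check(lambda x: x.transpose((1, 0)), [a])
        check(lambda x: x[1:3, ::2], [a])
        idx = np.array([0, 2, 2])
        check(lambda x: x[idx], [a])

    def test_concat_stack(self, rng):
        a = rng.standard_normal((2, 3))
        b = rng.standard_normal((2, 3))
        check(lambda x, y: concat([x, y], axis=1), [a, b])
        check(lambda x, y: stack([x, y], axis=0), [a, b])


def _direct_corr(x, w):
    n_b, ci, _, _, _ = x.shape
    co = w.shape[0]
    out = np.zeros((n_b, co) + x.shape[2:])
    for n in range(n_b):
        for o in range(co):
            for i in range(ci):
                out[n, o] += ndimage.correlate(x[n, i], w[o, i], mode="constant")
    return out


class TestConv3d:
    @pytest.mark.parametrize("k", [1, 3, 5, 7])
    def test_forward_matches_direct(self, rng, k):
        x = rng.standard_normal((2, 3, 6, 8, 7))
        w = rng.standard_normal((4, 3, k, k, k)) * 0.3
        y = conv3d(Tensor(x), Tensor(w))
        np.testing.assert_allclose(y.data, _direct_corr(x, w), atol=1e-10)

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_gradients(self, rng, k):
        x = rng.standard_normal((1, 2, 4, 5, 4))
        w = rng.standard_normal((2, 2, k, k, k)) * 0.3
        check(lambda a, b: conv3d(a, b), [x, w], tol=1e-5)

    def test_even_kernel_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            conv3d(Tensor(np.zeros((1, 1, 4, 4, 4))),
                   Tensor(np.zeros((1, 1, 2, 2, 2))))


class TestPoolingResize:
    def test_max_pool_forward(self, rng):
        x = rng.standard_normal((1, 1, 4, 4, 4))
        y = max_pool3d(Tensor(x))
        ref = x.reshape(1, 1, 2, 2, 2, 2, 2, 2).transpose(
            0, 1, 2, 4, 6, 3, 5, 7).reshape(1, 1, 2, 2, 2, 8).max(-1)
        np.testing.assert_array_equal(y.data, ref)

    def test_max_pool_grad(self, rng):
        x = rng.standard_normal((1, 2, 4, 4, 4))
        check(lambda a: max_pool3d(a), [x])

    def test_max_pool_odd_dims_rejected(self):
        with pytest.raises(ValueError, match="even"):
            max_pool3d(Tensor(np.zeros((1, 1, 3, 4, 4))))

    def test_upsample_shape_and_constant(self):
        x = Tensor(np.full((1, 1, 2, 2, 2), 3.5))
        y = upsample_trilinear_2x(x)
        assert y.shape == (1, 1, 4, 4, 4)
        np.testing.assert_allclose(y.data, 3.5)

    def test_upsample_grad(self, rng):
        x = rng.standard_normal((1, 1, 2, 4, 2))
        check(lambda a: upsample_trilinear_2x(a), [x])


class TestModules:
    def test_linear_and_lstm_grads(self, rng):
        lin = Linear(3, 2, rng)
        x = rng.standard_normal((4, 3))
        check(lambda a: lin(a), [x])
        lstm = LSTM(3, 4, 2, rng)
        xs = [Tensor(rng.standard_normal((2, 3)), requires_grad=True)
              for _ in range(3)]
        out = lstm(xs)
        total = out[0].sum()
        for o in out[1:]:
            total = total + o.sum()
        total.backward()
        assert all(x.grad is not None for x in xs)
        assert all(p.grad is not None for p in lstm.parameters())

    def test_state_dict_roundtrip(self, rng):
        lin = Linear(3, 2, rng)
        state = lin.state_dict()
        lin2 = Linear(3, 2, np.random.default_rng(99))
        lin2.load_state_dict(state)
        x = rng.standard_normal((2, 3))
        np.testing.assert_array_equal(lin(Tensor(x)).data, lin2(Tensor(x)).data)

    def test_adam_minimizes_quadratic(self, rng):
        from prostreg.nn import Parameter
        p = Parameter(np.array([5.0, -3.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            loss = (p * p).sum()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-2


def test_no_grad_blocks_graph(rng):
    x = Tensor(rng.standard_normal((2, 2)), requires_grad=True)
    with no_grad():
        y = x * 2.0
    assert not y.requires_grad


def test_backward_requires_scalar(rng):
    x = Tensor(rng.standard_normal((2, 2)), requires_grad=True)
    with pytest.raises(ValueError):
        (x * 1.0).backward()
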