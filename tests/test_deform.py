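"""Deformation operators: warping, composition, integration, diagnostics."""

import numpy as np
import pytest

from prostreg._autograd import Tensor
from prostreg.deform import compose, jacobian_stats, sample_field_at_points, vecint, warp
from prostreg.phantom import make_velocity_field


def euler_integrate(v, n_steps=1024):
    """Independent oracle: forward-Euler flow of a stationary velocity field."""
    phi = np.zeros_like(v)
    shape = v.shape[1:]
    grids = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    )
    for _ in range(n_steps):
        pts = (grids + phi).reshape(3, -1).T
        vv = sample_field_at_points(v, pts).T.reshape(v.shape)
        phi = phi + vv / n_steps
    return phi


INTERIOR = (slice(2, -2),) * 3


class TestWarp:
    def test_zero_field_identity_exact(self, rng):
        img = rng.standard_normal((8, 8, 8))
        phi = np.zeros((3, 8, 8, 8))
        np.testing.assert_array_equal(warp(img, phi), img)
        np.testing.assert_array_equal(warp(img, phi, mode="nearest"), img)

    def test_integer_shift_moves_impulse(self):
        img = np.zeros((8, 8, 8))
        img[4, 4, 4] = 1.0
        phi = np.zeros((3, 8, 8, 8))
        phi[0] = 2.0  # sample source at p + 2 along depth
        out = warp(img, phi, mode="nearest")
        assert out[2, 4, 4] == 1.0
        assert out.sum() == pytest.approx(1.0)

    def test_trilinear_exact_on_affine_images(self, rng):
        d, h, w = np.meshgrid(*[np.arange(10.0)] * 3, indexing="ij")
        img = 2.0 * d - 3.0 * h + 0.5 * w + 7.0
        phi = rng.uniform(-1.5, 1.5, (3, 10, 10, 10))
        out = warp(img, phi)
        expected = 2.0 * (d + phi[0]) - 3.0 * (h + phi[1]) + 0.5 * (w + phi[2]) + 7.0
        inside = (
            (d + phi[0] >= 0) & (d + phi[0] <= 9)
            & (h + phi[1] >= 0) & (h + phi[1] <= 9)
            & (w + phi[2] >= 0) & (w + phi[2] <= 9)
        )
        np.testing.assert_allclose(out[inside], expected[inside], atol=1e-9)

    def test_linear_in_image(self, rng):
        a = rng.standard_normal((6, 6, 6))
        b = rng.standard_normal((6, 6, 6))
        phi = rng.uniform(-1, 1, (3, 6, 6, 6))
        lhs = warp(2.0 * a + 3.0 * b, phi)
        rhs = 2.0 * warp(a, phi) + 3.0 * warp(b, phi)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            warp(np.zeros((4, 4, 4)), np.zeros((3, 4, 4, 4)), mode="cubic")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            warp(np.zeros((4, 4, 4)), np.zeros((3, 5, 4, 4)))

    def test_tensor_path_matches_numpy(self, rng):
        img = rng.standard_normal((5, 5, 5)).astype(np.float32)
        phi = rng.uniform(-1, 1, (3, 5, 5, 5)).astype(np.float32)
        out_np = warp(img, phi)
        out_t = warp(Tensor(img[None, None]), Tensor(phi[None]))
        np.testing.assert_allclose(out_t.data[0, 0], out_np, atol=1e-6)


class TestCompose:
    def test_identity_element(self, rng):
        phi = rng.uniform(-1, 1, (3, 8, 8, 8))
        zero = np.zeros_like(phi)
        np.testing.assert_allclose(compose(zero, phi), phi, atol=1e-12)
        np.testing.assert_allclose(compose(phi, zero), phi, atol=1e-12)

    def test_constant_translations_add(self):
        a = np.zeros((3, 10, 10, 10))
        b = np.zeros((3, 10, 10, 10))
        a[0], b[1] = 1.5, -2.0
        out = compose(a, b)
        np.testing.assert_allclose(out[0][INTERIOR], 1.5, atol=1e-10)
        np.testing.assert_allclose(out[1][INTERIOR], -2.0, atol=1e-10)

    def test_associativity_within_tolerance(self):
        fields = [
            vecint(make_velocity_field((12, 12, 12), 1.0, 4.0, seed=s))
            for s in range(3)
        ]
        lhs = compose(compose(fields[0], fields[1]), fields[2])
        rhs = compose(fields[0], compose(fields[1], fields[2]))
        assert np.abs(lhs - rhs)[(slice(None),) + INTERIOR].max() < 1e-2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose(np.zeros((3, 4, 4, 4)), np.zeros((3, 5, 4, 4)))


class TestVecint:
    def test_zero_velocity_identity(self):
        phi = vecint(np.zeros((3, 8, 8, 8)))
        np.testing.assert_array_equal(phi, 0.0)

    def test_constant_velocity_translates(self):
        v = np.zeros((3, 24, 24, 24))
        v[0] = 2.0
        phi = vecint(v)
        interior = (slice(8, -8),) * 3
        np.testing.assert_allclose(phi[0][interior], 2.0, atol=1e-3)
        np.testing.assert_allclose(phi[1][interior], 0.0, atol=1e-3)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_euler_oracle(self, seed):
        v = make_velocity_field((16, 16, 16), 2.0, 4.0, seed=seed)
        phi = vecint(v, steps=7)
        oracle = euler_integrate(v, 1024)
        err = np.sqrt(((phi - oracle) ** 2).sum(axis=0))[INTERIOR].max()
        assert err < 0.05

    def test_inverse_consistency(self):
        v = make_velocity_field((16, 16, 16), 2.0, 4.0, seed=11)
        resid = compose(vecint(-v), vecint(v))
        assert np.sqrt((resid ** 2).sum(axis=0))[INTERIOR].max() < 0.1

    def test_scaling_squaring_recursion_exact(self):
        v = make_velocity_field((12, 12, 12), 1.5, 4.0, seed=5)
        lhs = vecint(2.0 * v, steps=8)
        phi = vecint(v, steps=7)
        rhs = compose(phi, phi)
        np.testing.assert_array_equal(lhs, rhs)

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            vecint(np.zeros((3, 8, 8, 8)), steps=-1)

    def test_differentiable_path(self, rng):
        v = Tensor(rng.uniform(-0.5, 0.5, (1, 3, 8, 8, 8)), requires_grad=True)
        phi = vecint(v, steps=3)
        (phi * phi).sum().backward()
        assert v.grad is not None and np.all(np.isfinite(v.grad))


class TestJacobian:
    def test_identity_field(self):
        stats = jacobian_stats(np.zeros((3, 8, 8, 8)))
        np.testing.assert_allclose(stats["det_field"], 1.0)
        assert stats["folding_fraction"] == 0.0

    def test_uniform_scaling(self):
        shape = (10, 10, 10)
        grids = np.stack(
            np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
        )
        center = (np.array(shape, dtype=np.float64) - 1) / 2
        phi = 0.1 * (grids - center.reshape(3, 1, 1, 1))
        stats = jacobian_stats(phi)
        np.testing.assert_allclose(
            stats["det_field"][1:-1, 1:-1, 1:-1], 1.1 ** 3, atol=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1])
    def test_integrated_smooth_fields_do_not_fold(self, seed):
        v = make_velocity_field((16, 16, 16), 3.0, 4.0, seed=seed)
        assert jacobian_stats(vecint(v))["folding_fraction"] == 0.0
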