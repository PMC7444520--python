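"""Affine grid, bilinear sampler and the spatial transformer, checked
against scalar brute-force oracles and finite differences."""

import numpy as np
import pytest

from painstn.stn import (
    IDENTITY_THETA,
    LocalizationNet,
    SpatialTransformer,
    _bilinear_backward,
    _bilinear_forward,
    affine_grid,
    affine_grid_backward,
    bilinear_sample,
)


def grid_oracle(theta, out_h, out_w):
    """Per-pixel loop applying the 2x3 matrix to target coordinates."""
    a = np.asarray(theta, dtype=float).reshape(2, 3)
    xs = np.linspace(-1, 1, out_w) if out_w > 1 else [0.0]
    ys = np.linspace(-1, 1, out_h) if out_h > 1 else [0.0]
    out = np.zeros((out_h, out_w, 2))
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            out[i, j] = a @ np.array([x, y, 1.0])
    return out


def sample_oracle(source, grid):
    """Scalar double-loop bilinear interpolation with zero padding."""
    n, c, h, w = source.shape
    _, ho, wo, _ = grid.shape
    out = np.zeros((n, c, ho, wo))
    for b in range(n):
        for i in range(ho):
            for j in range(wo):
                x = (grid[b, i, j, 0] + 1) * (w - 1) / 2
                y = (grid[b, i, j, 1] + 1) * (h - 1) / 2
                x0, y0 = int(np.floor(x)), int(np.floor(y))
                for dy in (0, 1):
                    for dx in (0, 1):
                        xc, yc = x0 + dx, y0 + dy
                        if 0 <= xc < w and 0 <= yc < h:
                            wgt = (x - x0 if dx else 1 - (x - x0)) * (y - y0 if dy else 1 - (y - y0))
                            out[b, :, i, j] += wgt * source[b, :, yc, xc]
    return out


class TestAffineGrid:
    def test_identity_theta_gives_target_grid(self):
        g = affine_grid(IDENTITY_THETA, 5, 7)
        assert np.allclose(g[0, ..., 0], np.linspace(-1, 1, 7)[None, :])
        assert np.allclose(g[0, ..., 1], np.linspace(-1, 1, 5)[:, None])

    def test_pure_translation_shifts_x_only(self):
        t = 0.3
        g = affine_grid([1, 0, t, 0, 1, 0], 4, 4)
        ref = affine_grid(IDENTITY_THETA, 4, 4)
        assert np.allclose(g[..., 0], ref[..., 0] + t)
        assert np.allclose(g[..., 1], ref[..., 1])

    def test_matches_brute_force_oracle(self, rng):
        theta = rng.normal(size=6)
        g = affine_grid(theta, 5, 7)
        assert np.allclose(g[0], grid_oracle(theta, 5, 7), atol=1e-12)

    def test_linear_in_theta(self, rng):
        """grid(a*t1 + (1-a)*t2) == a*grid(t1) + (1-a)*grid(t2) pointwise."""
        t1, t2 = rng.normal(size=6), rng.normal(size=6)
        for alpha in (0.0, 0.3, 1.0):
            mix = alpha * t1 + (1 - alpha) * t2
            expect = alpha * affine_grid(t1, 6, 6) + (1 - alpha) * affine_grid(t2, 6, 6)
            assert np.allclose(affine_grid(mix, 6, 6), expect, atol=1e-12)

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(ValueError):
            affine_grid([1, 0, np.nan, 0, 1, 0], 4, 4)

    def test_backward_matches_finite_differences(self, rng):
        theta = rng.normal(size=6)
        dgrid = rng.normal(size=(1, 5, 4, 2))
        ana = affine_grid_backward(dgrid)[0]
        eps = 1e-6
        for i in range(6):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = ((affine_grid(tp, 5, 4) - affine_grid(tm, 5, 4)) * dgrid).sum() / (2 * eps)
            assert abs(num - ana[i]) < 1e-5


class TestBilinearSample:
    def test_identity_grid_reproduces_input(self, rng):
        u = rng.random((2, 3, 8, 8))
        g = np.broadcast_to(affine_grid(IDENTITY_THETA, 8, 8), (2, 8, 8, 2)).copy()
        assert np.allclose(bilinear_sample(u, g), u, atol=1e-12)

    def test_fully_out_of_bounds_grid_is_zero(self, rng):
        u = rng.random((1, 3, 6, 6))
        g = np.full((1, 4, 4, 2), 5.0)  # far outside [-1, 1]^2
        assert np.all(bilinear_sample(u, g) == 0.0)

    def test_matches_scalar_oracle(self, rng):
        u = rng.random((2, 2, 8, 8))
        g = rng.uniform(-1.4, 1.4, size=(2, 5, 6, 2))
        v = bilinear_sample(u, g)
        assert np.allclose(v, sample_oracle(u, g), rtol=1e-6, atol=1e-12)

    def test_output_within_contributing_pixel_range(self, rng):
        """Each output lies in [min, max] of the four source neighbors,
        with 0 included whenever a corner is out of bounds."""
        u = rng.random((1, 1, 8, 8)) + 0.5
        g = rng.uniform(-1.3, 1.3, size=(1, 10, 10, 2))
        v = bilinear_sample(u, g)
        assert np.all(v >= 0.0)
        assert np.all(v <= u.max() + 1e-12)

    def test_gradients_match_finite_differences(self, rng):
        u = rng.random((1, 2, 6, 6))
        g = rng.uniform(-0.9, 0.9, size=(1, 4, 3, 2))
        dout = rng.normal(size=(1, 2, 4, 3))
        out, cache = _bilinear_forward(u, g)
        du, dg = _bilinear_backward(cache, dout)
        eps = 1e-6
        for _ in range(10):
            i = tuple(rng.integers(s) for s in u.shape)
            up, um = u.copy(), u.copy()
            up[i] += eps
            um[i] -= eps
            num = ((bilinear_sample(up, g) - bilinear_sample(um, g)) * dout).sum() / (2 * eps)
            assert abs(num - du[i]) < 1e-5
        for _ in range(10):
            i = tuple(rng.integers(s) for s in g.shape)
            gp, gm = g.copy(), g.copy()
            gp[i] += eps
            gm[i] -= eps
            num = ((bilinear_sample(u, gp) - bilinear_sample(u, gm)) * dout).sum() / (2 * eps)
            assert abs(num - dg[i]) < 1e-5

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            bilinear_sample(rng.random((2, 3, 4, 4)), rng.random((1, 4, 4, 2)))


class TestLocalizationNet:
    def test_identity_init_outputs_identity_theta(self, rng):
        net = LocalizationNet(image_size=24, n_filters=4)
        x = rng.random((2, 3, 24, 24))
        assert np.allclose(net(x), IDENTITY_THETA[None, :])

    def test_canonical_dimension_bookkeeping(self, rng):
        """192 -> 96 -> 48 -> 24 -> 12 -> 6 -> 3 through six blocks; the
        flatten is 3*3*16 = 144 wide."""
        net = LocalizationNet(image_size=192, n_filters=16, identity_init=False)
        assert net.flat_width == 144
        theta = net(rng.random((1, 3, 192, 192)))
        assert theta.shape == (1, 6)
        assert np.all(np.isfinite(theta))

    def test_wrong_input_shape_rejected(self, rng):
        net = LocalizationNet(image_size=24, n_filters=4)
        with pytest.raises(ValueError):
            net(rng.random((1, 3, 48, 48)))

    def test_invalid_image_size_rejected(self):
        with pytest.raises(ValueError):
            LocalizationNet(image_size=50)


class TestSpatialTransformer:
    def test_identity_initialized_stn_is_noop(self, rng):
        stn = SpatialTransformer(image_size=24, n_filters=4)
        x = rng.random((2, 3, 24, 24))
        assert np.allclose(stn(x), x, atol=1e-12)

    def test_output_bounded_by_input_range(self, rng):
        stn = SpatialTransformer(image_size=24, n_filters=4, identity_init=False)
        x = rng.random((2, 3, 24, 24))
        v = stn(x)
        assert v.min() >= -1e-12 and v.max() <= x.max() + 1e-12

    def test_gradient_flows_to_localization(self, rng):
        stn = SpatialTransformer(image_size=24, n_filters=4, identity_init=False)
        x = rng.random((1, 3, 24, 24))
        v = stn(x)
        stn.backward(np.ones_like(v))
        grads = [np.abs(p.grad).sum() for p in stn.parameters()]
        assert sum(grads) > 0

    def test_two_pass_composition_matches_composed_matrix(self):
        """Two sampling passes with A then B agree with one pass using the
        composed affine, up to interpolation error, on a smooth image."""
        s = 33
        yy, xx = np.mgrid[0:s, 0:s] / (s - 1)
        img = (np.sin(2 * np.pi * xx) * np.cos(2 * np.pi * yy) * 0.25 + 0.5)[None, None]
        a = np.array([1.05, 0.1, 0.05, -0.08, 0.95, -0.03])
        b = np.array([0.9, -0.05, 0.02, 0.06, 1.1, 0.04])
        one = bilinear_sample(img, affine_grid(a, s, s))
        two = bilinear_sample(one, affine_grid(b, s, s))
        am, bm = a.reshape(2, 3), b.reshape(2, 3)
        comp = np.hstack([am[:, :2] @ bm[:, :2], (am[:, :2] @ bm[:, 2:] + am[:, 2:])]).ravel()
        direct = bilinear_sample(img, affine_grid(comp, s, s))
        # compare away from the zero-padded border
        inner = (slice(None), slice(None), slice(6, -6), slice(6, -6))
        assert np.abs(two[inner] - direct[inner]).max() < 0.02
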