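"""Spatial transformer: localization network, affine grid, bilinear sampler.

The transformer predicts a 2-D affine transform theta = (t11, t12, t13,
t21, t22, t23) from the input image, builds a sampling grid by applying
the 2x3 matrix to the regular target grid in normalized coordinates, and
resamples the input bilinearly at those source locations.  Normalized
coordinates span [-1, 1] with (-1, -1) the center of the top-left pixel
(align-corners convention); source coordinates falling outside the image
contribute zero, which produces the characteristic black edges after
rotation or zoom-out.

The grid/sampling primitives are plain functions (with explicit backward
companions) so they can be checked against scalar brute-force loops; the
``SpatialTransformer`` class wires them to the localization CNN for
end-to-end training.
"""

from __future__ import annotations

import numpy as np

from .nn import Conv2d, Flatten, Linear, MaxPool2, Module, ReLU, Sequential

IDENTITY_THETA = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


def _as_theta_batch(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = theta[None, :]
    if theta.ndim != 2 or theta.shape[1] != 6:
        raise ValueError(f"theta must have 6 components per item, got shape {theta.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta contains non-finite values")
    return theta


def affine_grid(theta: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Sampling grid of source coordinates for an ``out_h x out_w`` output.

    For every target location (x_t, y_t) on the regular normalized grid,
    the source location is A_theta @ (x_t, y_t, 1).  Returns an array of
    shape (N, out_h, out_w, 2) with the last axis ordered (x_s, y_s);
    a 1-D theta yields N=1.
    """
    if out_h < 1 or out_w < 1:
        raise ValueError("output grid dimensions must be >= 1")
    in_dtype = np.asarray(theta).dtype
    th = _as_theta_batch(theta).reshape(-1, 2, 3)
    xt = np.linspace(-1.0, 1.0, out_w) if out_w > 1 else np.zeros(1)
    yt = np.linspace(-1.0, 1.0, out_h) if out_h > 1 else np.zeros(1)
    xx, yy = np.meshgrid(xt, yt)
    tgt = np.stack([xx, yy, np.ones_like(xx)], axis=-1)  # (H, W, 3)
    # (N, H, W, 2) = tgt (H, W, 3) . th^T (N, 3, 2)
    grid = np.einsum("hwk,njk->nhwj", tgt, th)
    return grid.astype(in_dtype) if np.issubdtype(in_dtype, np.floating) else grid


def affine_grid_backward(dgrid: np.ndarray) -> np.ndarray:
    """Gradient of ``affine_grid`` with respect to theta.

    ``dgrid`` is (N, H, W, 2); returns (N, 6) ordered like theta.
    """
    n, h, w, _ = dgrid.shape
    xt = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1)
    yt = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1)
    xx, yy = np.meshgrid(xt, yt)
    tgt = np.stack([xx, yy, np.ones_like(xx)], axis=-1)  # (H, W, 3)
    dth = np.einsum("nhwj,hwk->njk", dgrid, tgt)  # (N, 2, 3)
    return dth.reshape(n, 6)


def bilinear_sample(source: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Sample ``source`` (N, C, H, W) at normalized grid locations.

    Each output pixel interpolates the four nearest source pixels; any
    corner outside the source contributes zero.  Returns (N, C, Ho, Wo).
    """
    out, _ = _bilinear_forward(source, grid)
    return out


def _bilinear_forward(source: np.ndarray, grid: np.ndarray):
    source = np.asarray(source)
    if not np.issubdtype(source.dtype, np.floating):
        source = source.astype(np.float64)
    # interpolation weights follow the source dtype so float32 networks
    # are not silently promoted to float64
    grid = np.asarray(grid, dtype=source.dtype)
    if source.ndim != 4:
        raise ValueError(f"source must be (N, C, H, W), got shape {source.shape}")
    if grid.ndim != 4 or grid.shape[-1] != 2 or grid.shape[0] != source.shape[0]:
        raise ValueError(f"grid must be (N, Ho, Wo, 2) matching batch, got shape {grid.shape}")
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid contains non-finite coordinates")
    n, c, h, w = source.shape
    # normalized [-1, 1] -> pixel coordinates, corners aligned to pixel centers
    ix = (grid[..., 0] + 1.0) * (w - 1) / 2.0
    iy = (grid[..., 1] + 1.0) * (h - 1) / 2.0
    x0 = np.floor(ix).astype(np.int64)
    y0 = np.floor(iy).astype(np.int64)
    fx = ix - x0
    fy = iy - y0

    src_flat = source.transpose(0, 2, 3, 1).reshape(n, h * w, c)
    nn_idx = np.arange(n)[:, None, None]
    out = 0.0
    corners = []
    for dy, wy in ((0, 1.0 - fy), (1, fy)):
        for dx, wx in ((0, 1.0 - fx), (1, fx)):
            xc, yc = x0 + dx, y0 + dy
            valid = (xc >= 0) & (xc < w) & (yc >= 0) & (yc < h)
            flat = np.clip(yc, 0, h - 1) * w + np.clip(xc, 0, w - 1)
            vals = src_flat[nn_idx, flat]  # (N, Ho, Wo, C)
            wgt = (wx * wy * valid)[..., None]
            out = out + wgt * vals
            corners.append((dx, dy, valid, flat, vals))
    out = out.transpose(0, 3, 1, 2)
    cache = (source.shape, fx, fy, corners, grid.dtype)
    return out, cache


def _bilinear_backward(cache, dout: np.ndarray):
    """Gradients of the sampler w.r.t. source values and the grid."""
    (n, c, h, w), fx, fy, corners, _ = cache
    dg = dout.transpose(0, 2, 3, 1)  # (N, Ho, Wo, C)
    dsrc_flat = np.zeros((n, h * w, c), dtype=dout.dtype)
    batch_off = np.arange(n)[:, None, None] * (h * w)
    dix = np.zeros_like(fx)
    diy = np.zeros_like(fy)
    for dx_off, dy_off, valid, flat, vals in corners:
        wx = fx if dx_off == 1 else 1.0 - fx
        wy = fy if dy_off == 1 else 1.0 - fy
        sx = 1.0 if dx_off == 1 else -1.0
        sy = 1.0 if dy_off == 1 else -1.0
        contrib = dg * (wx * wy * valid)[..., None]
        idx = (batch_off + flat).ravel()
        for ch in range(c):
            acc = np.bincount(idx, weights=contrib[..., ch].ravel(), minlength=n * h * w)
            dsrc_flat[:, :, ch] += acc.reshape(n, h * w).astype(dout.dtype)
        dot = (dg * vals).sum(axis=-1) * valid
        dix += dot * sx * wy
        diy += dot * wx * sy
    dsource = dsrc_flat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
    dgrid = np.stack([dix * (w - 1) / 2.0, diy * (h - 1) / 2.0], axis=-1)
    return dsource, dgrid


class BilinearSampler(Module):
    """Module wrapper: forward takes (source, grid) via ``sample``."""

    def sample(self, source: np.ndarray, grid: np.ndarray) -> np.ndarray:
        out, self._cache = _bilinear_forward(source, grid)
        return out

    def backward(self, dout: np.ndarray):
        return _bilinear_backward(self._cache, dout)


class LocalizationNet(Module):
    """Small CNN regressing the 6 affine parameters.

    Repeated blocks of (3x3 conv -> ReLU -> 2x2 max-pool) with a fixed
    filter width reduce the spatial size from ``image_size`` down to 3
    (the input size must be 3 * 2**k), followed by FC -> ReLU -> FC(6).
    At the canonical 192x192 input with 16 filters this is six blocks and
    a 3*3*16 = 144-wide flatten feeding FC(144 -> 32) -> ReLU -> FC(32 -> 6).

    With ``identity_init`` the final FC starts from the identity
    transform: its bias is the identity theta and its He-initialized
    weights are multiplied by ``head_damp`` (default 0, i.e. exactly
    zero weights, so an untrained transformer is exactly a no-op).
    A small nonzero ``head_damp`` keeps the start near-identity while
    letting gradient reach the localization body from the first step —
    with a zero head the chain rule multiplies every body gradient by
    the head weights, so the body cannot learn input-dependent
    localization until the head has drifted away from zero.
    """

    def __init__(
        self,
        image_size: int = 192,
        in_channels: int = 3,
        n_filters: int = 16,
        rng: np.random.Generator | None = None,
        fan_mode: str = "full",
        identity_init: bool = True,
        head_damp: float = 0.0,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        n_blocks = _n_halvings(image_size)
        if n_blocks < 1:
            raise ValueError("image_size must allow at least one conv/pool block (>= 6)")
        self.image_size = image_size
        self.in_channels = in_channels
        layers: list[Module] = []
        ch = in_channels
        for b in range(n_blocks):
            layers += [
                Conv2d(ch, n_filters, rng=rng, fan_mode=fan_mode, name=f"loc.conv{b}"),
                ReLU(),
                MaxPool2(),
            ]
            ch = n_filters
        self.flat_width = 3 * 3 * n_filters
        layers += [Flatten(), Linear(self.flat_width, 32, rng=rng, name="loc.fc1"), ReLU()]
        self.body = Sequential(*layers)
        self.head = Linear(32, 6, rng=rng, name="loc.fc2")
        if identity_init:
            self.head.weight.value *= head_damp
            self.head.bias.value[...] = IDENTITY_THETA

    def parameters(self):
        return self.body.parameters() + self.head.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels or x.shape[2] != self.image_size or x.shape[3] != self.image_size:
            raise ValueError(
                f"expected (N, {self.in_channels}, {self.image_size}, {self.image_size}) input, got {x.shape}"
            )
        return self.head(self.body(x))

    def backward(self, dtheta: np.ndarray) -> np.ndarray:
        return self.body.backward(self.head.backward(dtheta))


def _n_halvings(image_size: int) -> int:
    """Number of 2x2 pools taking ``image_size`` down to 3."""
    size, n = image_size, 0
    while size > 3 and size % 2 == 0:
        size //= 2
        n += 1
    if size != 3:
        raise ValueError(f"image_size must be 3 * 2**k for some k >= 0, got {image_size}")
    return n


class SpatialTransformer(Module):
    """Localization net + grid generator + sampler, end to end.

    ``forward`` stores the predicted thetas in ``last_theta`` for logging.

    ``identity_anchor`` adds the gradient of a quadratic penalty
    anchor * mean(||theta - identity||^2) during backward.  The sampler's
    loss surface is treacherous: once theta maps the grid mostly outside
    the image, the output goes black and the gradient signal dies, so a
    runaway transform is an absorbing state.  A small anchor makes the
    identity attractive enough to prevent the runaway while data
    gradients can still pull theta toward genuinely useful transforms
    (e.g. zooming onto the face).  Default 0 (no anchor).
    """

    def __init__(
        self,
        image_size: int = 192,
        in_channels: int = 3,
        n_filters: int = 16,
        rng: np.random.Generator | None = None,
        fan_mode: str = "full",
        identity_init: bool = True,
        head_damp: float = 0.0,
        identity_anchor: float = 0.0,
    ):
        self.localization = LocalizationNet(
            image_size, in_channels, n_filters, rng=rng, fan_mode=fan_mode,
            identity_init=identity_init, head_damp=head_damp,
        )
        self.sampler = BilinearSampler()
        self.image_size = image_size
        self.identity_anchor = identity_anchor
        self.last_theta: np.ndarray | None = None

    def parameters(self):
        return self.localization.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        theta = self.localization(x)
        self.last_theta = theta
        grid = affine_grid(theta, x.shape[2], x.shape[3])
        return self.sampler.sample(x, grid)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsource, dgrid = self.sampler.backward(dout)
        dtheta = affine_grid_backward(dgrid).astype(dout.dtype)
        if self.identity_anchor > 0.0:
            n = dtheta.shape[0]
            dtheta = dtheta + (2.0 * self.identity_anchor / n) * (
                self.last_theta - IDENTITY_THETA.astype(dout.dtype)
            )
        dx_loc = self.localization.backward(dtheta)
        return dsource + dx_loc


def localization_forward(image: np.ndarray, net: LocalizationNet) -> np.ndarray:
    """Run a localization network on one (H, W, C) image; returns theta (6,)."""
    x = np.asarray(image, dtype=float).transpose(2, 0, 1)[None]
    return net(x)[0]
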