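"""Ground-truth synthetic data: known templates, bases and latents.

The generator samples from the model's own generative process — smooth
basis fields drawn by Green's-function smoothing of white noise, Gaussian
latents, geodesic shooting, warping and the chosen noise model — so that
fitting can be validated against a known answer.  Missing data is emulated
with randomly placed rectangles (wrapping around the periodic field of
view) set to NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import likelihoods as lk
from .diffeo import geodesic_shoot, pull
from .model import FitConfig, ModelParams, Operators, reconstruct
from .operators import GridSpec


@dataclass
class GroundTruth:
    """A known model with the latents and rendered images drawn from it."""

    params: ModelParams
    config: FitConfig
    ops: Operators
    z_true: np.ndarray  # (K, N)
    images: list  # of ObservedImage
    masks: list  # True where hidden


def _smooth_noise(op, shape, rng, normalise=None):
    """Green's-smoothed white noise: one draw from the operator's prior
    (up to scale) obtained by applying the inverse operator to N(0, I)."""
    w = op.apply_inverse(rng.standard_normal(shape))
    if normalise == "max":
        w = w / max(np.abs(w).max(), 1e-30)
    elif normalise == "rms":
        w = w / max(np.sqrt(np.mean(w**2)), 1e-30)
    return w


def _blob(grid: GridSpec, centre, radius):
    """Smooth radial bump exp(−r²/2radius²) with periodic distance."""
    r2 = np.zeros(grid.dims)
    for ax, n in enumerate(grid.dims):
        x = np.arange(n, dtype=float)
        dx = np.minimum(np.abs(x - centre[ax]), n - np.abs(x - centre[ax]))
        shape = [1] * grid.ndim
        shape[ax] = n
        r2 = r2 + (dx.reshape(shape)) ** 2
    return np.exp(-0.5 * r2 / radius**2)


def _template(grid: GridSpec, noise: str, rng=None, eps=1e-2, centre_offset=None):
    """A multi-blob template in the noise model's natural parameterisation.

    The Gaussian-model template carries smooth random texture on top of the
    blobs: without intensity gradients across the whole field of view,
    velocity components over flat regions would be unidentifiable (the
    aperture problem) and recovery experiments would be meaningless.
    ``centre_offset`` (voxels per axis) relocates the figure, giving
    structurally distinct class templates for classification experiments.
    """
    if centre_offset is None:
        centre_offset = (0.0,) * grid.ndim
    c = [n / 2 + o for n, o in zip(grid.dims, centre_offset)]
    r = min(grid.dims) / 5.0
    main = _blob(grid, c, r)
    off = [ci + min(grid.dims) / 5 for ci in c]
    second = 0.6 * _blob(grid, off, r / 2)
    intensity = np.clip(main + second, 0.0, 1.0)
    if noise == lk.GAUSSIAN:
        from scipy.ndimage import gaussian_filter

        rng = rng or np.random.default_rng(0)
        tex = gaussian_filter(rng.standard_normal(grid.dims), 2.5, mode="wrap")
        tex *= 0.5 / max(np.abs(tex).max(), 1e-30)
        return intensity + tex
    if noise == lk.BERNOULLI:
        p = np.clip(intensity, eps, 1 - eps)
        return np.log(p) - np.log1p(-p)
    inner = _blob(grid, c, r / 2)
    fg = np.clip(intensity - inner, 0, 1)
    bg = np.clip(1.0 - intensity, eps, 1)
    probs = np.stack([np.clip(inner, eps, 1), np.clip(fg, eps, 1), bg], axis=-1)
    probs = probs / probs.sum(axis=-1, keepdims=True)
    return np.log(probs)


def make_ground_truth_model(
    grid: GridSpec,
    K: int = 3,
    rng=None,
    config: FitConfig = None,
    displacement: float = 2.5,
    appearance_amp: float = 0.35,
    centre_offset=None,
) -> GroundTruth:
    """Sample a known model: smooth bases, blob template, Â = I.

    Velocity basis columns are Green's-smoothed white noise rescaled so the
    peak speed is ``displacement`` voxels; appearance columns likewise with
    peak amplitude ``appearance_amp`` (in the natural parameter scale of
    the noise model).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    config = config or FitConfig(K=K)
    if config.K != K:
        raise ValueError("config.K must match K")
    ops = Operators.from_config(grid, config)
    d = grid.ndim
    mu = _template(grid, config.noise, rng, centre_offset=centre_offset)
    amp_a = appearance_amp if config.noise == lk.GAUSSIAN else 4.0 * appearance_amp
    Wa = np.stack(
        [
            amp_a * _smooth_noise(ops.La, mu.shape, rng, normalise="max")
            for _ in range(config.Ka)
        ]
    )
    Wv = np.stack(
        [
            displacement
            * _smooth_noise(ops.Lv, grid.dims + (d,), rng, normalise="max")
            for _ in range(config.Kv)
        ]
    )
    A_hat = np.eye(config.K)
    sigma2 = 1.0
    params = ModelParams(grid, config.mode, config.noise, mu, Wa, Wv, sigma2, A_hat)
    return GroundTruth(params, config, ops, None, [], [])


def random_rectangle_mask(dims, fraction, rng):
    """Boolean mask of a randomly placed rectangle covering ``fraction`` of
    the lattice, wrapping around the periodic edges.

    Side lengths are chosen per axis near fraction^(1/d) of each dim, with
    the last axis adjusted so the covered area is exact whenever the target
    voxel count factorises (e.g. 25% of even dims)."""
    d = len(dims)
    target = fraction * np.prod(dims)
    # search near-cubic integer side lengths whose product hits the target
    # exactly when it is attainable (e.g. 25% of even dims)
    ideal = [n * fraction ** (1.0 / d) for n in dims]
    best, best_cost = None, None
    ranges = [
        range(max(1, round(i) - 3), min(n, round(i) + 3) + 1)
        for i, n in zip(ideal[:-1], dims[:-1])
    ]
    for combo in itertools.product(*ranges):
        rest = target / np.prod(combo)
        last = int(np.clip(round(rest), 1, dims[-1]))
        err = abs(np.prod(combo) * last - target)
        aspect = sum((s - i) ** 2 for s, i in zip(combo + (last,), ideal))
        cost = (err, aspect)
        if best is None or cost < best_cost:
            best, best_cost = combo + (last,), cost
    sides = list(best)
    mask = np.zeros(dims, dtype=bool)
    corner = [rng.integers(0, n) for n in dims]
    slabs = []
    for n, c, s in zip(dims, corner, sides):
        idx = (np.arange(c, c + s) % n)
        slabs.append(idx)
    mask[np.ix_(*slabs)] = True
    return mask


def apply_missing_rectangles(images, fraction, rng, noise):
    """NaN out one wrapped rectangle per image; returns (masked, masks)."""
    masked, masks = [], []
    for im in images:
        im = np.asarray(im, dtype=float).copy()
        dims = im.shape[:-1] if noise == lk.CATEGORICAL else im.shape
        m = random_rectangle_mask(dims, fraction, rng)
        if noise == lk.CATEGORICAL:
            im[m, :] = np.nan
        else:
            im[m] = np.nan
        masked.append(im)
        masks.append(m)
    return masked, masks


def render_dataset(
    gt: GroundTruth,
    N: int,
    rng,
    noise_level: float = 0.05,
    missing_fraction: float = 0.0,
    sample_discrete: bool = False,
):
    """Draw z ~ N(0, Â⁻¹), reconstruct, shoot, warp and observe.

    Gaussian: additive noise of s.d. ``noise_level`` (the model's σ is set
    accordingly).  Bernoulli/categorical: soft probability maps by default,
    or hard draws with ``sample_discrete``.  ``missing_fraction`` > 0 NaNs
    a wrapped rectangle of that area in every image.  Returns the populated
    GroundTruth (images, z_true, masks filled in).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p, cfg, ops = gt.params, gt.config, gt.ops
    K = cfg.K
    A = 0.5 * (p.A_hat + p.A_hat.T)
    Lchol = np.linalg.cholesky(np.linalg.inv(A))
    Z = Lchol @ rng.standard_normal((K, N))
    images, masks = [], []
    if p.noise == lk.GAUSSIAN and noise_level > 0:
        p.sigma2 = float(noise_level**2)
    for n in range(N):
        a, v = reconstruct(p, Z[:, n])
        defm = geodesic_shoot(v, ops.Lv, cfg.n_shoot_steps)
        ap = pull(a, defm)
        img = lk.expected_image(ap, p.noise)
        if p.noise == lk.GAUSSIAN and noise_level > 0:
            img = img + noise_level * rng.standard_normal(img.shape)
        elif sample_discrete and p.noise == lk.BERNOULLI:
            img = (rng.random(img.shape) < img).astype(float)
        elif sample_discrete and p.noise == lk.CATEGORICAL:
            flat = img.reshape(-1, img.shape[-1])
            cum = np.cumsum(flat, axis=-1)
            u = rng.random(flat.shape[0])[:, None]
            idx = (u > cum).sum(axis=-1)
            img = np.eye(img.shape[-1])[idx].reshape(img.shape)
        dims = img.shape[:-1] if p.noise == lk.CATEGORICAL else img.shape
        if missing_fraction > 0:
            m = random_rectangle_mask(dims, missing_fraction, rng)
            if p.noise == lk.CATEGORICAL:
                img = img.copy()
                img[m, :] = np.nan
            else:
                img = img.copy()
                img[m] = np.nan
        else:
            m = np.zeros(dims, dtype=bool)
        images.append(lk.ObservedImage(img, p.noise))
        masks.append(m)
    gt.z_true = Z
    gt.images = images
    gt.masks = masks
    return gt
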