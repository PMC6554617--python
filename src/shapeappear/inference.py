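"""Using a fitted model: encoding, evidence, classification, sampling,
imputation, and overlap scoring.

New images are encoded by Gauss-Newton optimisation of their latent code
against the frozen model; the local Hessian gives a Laplace approximation
q(z) = N(ẑ, S⁻¹) from which the marginal likelihood of the image under the
model is approximated as

    log ∫ p(f, z | M) dz ≈ log p(f, ẑ | M) − ½ log|S| + (K/2) log 2π.

Generative classification compares this evidence across independently
trained class models.  Imputation encodes from the observed voxels only and
reads the model's expected image everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import likelihoods as lk
from .diffeo import geodesic_shoot, pull
from .model import (
    FitConfig,
    ModelParams,
    Operators,
    latent_gn,
    reconstruct,
)


@dataclass
class Encoding:
    """Latent mode, Laplace precision and model evidence for one image."""

    z_hat: np.ndarray
    precision: np.ndarray  # Gauss-Newton Hessian at the mode (K×K)
    log_evidence: float
    energy: float


@dataclass
class ClassPosterior:
    """Per-class probabilities from generative model comparison."""

    probs: np.ndarray
    log_evidences: np.ndarray
    labels: list


def _logdet_floored(M, floor=1e-10):
    vals = np.linalg.eigvalsh(0.5 * (M + M.T))
    vals = np.maximum(vals, floor)
    return float(np.sum(np.log(vals)))


def encode(
    f: lk.ObservedImage,
    params: ModelParams,
    config: FitConfig,
    ops: Operators = None,
    n_iter: int = 12,
    z0: np.ndarray = None,
) -> Encoding:
    """Fit the latent code of a single image against a frozen model."""
    ops = ops or Operators.from_config(params.grid, config)
    K = config.K
    Ga = ops.La.gram(list(params.Wa))
    Gv = ops.Lv.gram(list(params.Wv))
    if config.mode == "shared":
        Gfull = Ga + Gv
    else:
        Gfull = np.zeros((K, K))
        Gfull[: config.Ka, : config.Ka] = Ga
        Gfull[config.Ka :, config.Ka :] = Gv
    P0 = config.lambda1 * params.A_hat + config.lambda2 * Gfull
    P0 = 0.5 * (P0 + P0.T)
    z0 = np.zeros(K) if z0 is None else np.asarray(z0, dtype=float)
    z, H, energy, _ = latent_gn(f, params, ops, config, z0, P0, n_iter=n_iter)
    if not np.isfinite(energy):
        raise FloatingPointError("non-finite energy while encoding")
    # log p(f, ẑ | M) with the λ-weighted latent prior, Laplace-corrected
    log_joint = (
        -energy
        - 0.5 * float(z @ P0 @ z)
        + 0.5 * _logdet_floored(P0)
        - 0.5 * K * np.log(2.0 * np.pi)
    )
    log_ev = log_joint - 0.5 * _logdet_floored(H) + 0.5 * K * np.log(2.0 * np.pi)
    return Encoding(z, 0.5 * (H + H.T), float(log_ev), float(energy))


def classify(
    f: lk.ObservedImage,
    models,
    priors=None,
    configs=None,
    ops=None,
    n_iter: int = 12,
    labels=None,
) -> ClassPosterior:
    """Softmax of per-class (log evidence + log prior) over fitted models.

    ``models`` is a list of (params, config) pairs, or of params with a
    shared ``configs`` list.  Priors default to uniform.
    """
    pairs = []
    for i, m in enumerate(models):
        if isinstance(m, tuple):
            pairs.append(m)
        else:
            pairs.append((m, configs[i] if isinstance(configs, (list, tuple)) else configs))
    n = len(pairs)
    if priors is None:
        priors = np.full(n, 1.0 / n)
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()
    log_evs = np.empty(n)
    for i, (params, config) in enumerate(pairs):
        op_i = ops[i] if isinstance(ops, (list, tuple)) else ops
        log_evs[i] = encode(f, params, config, ops=op_i, n_iter=n_iter).log_evidence
    score = log_evs + np.log(priors)
    score -= score.max()
    p = np.exp(score)
    p /= p.sum()
    if labels is None:
        labels = list(range(n))
    return ClassPosterior(p, log_evs, labels)


def sample_latents(A_hat: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n latent vectors z ~ N(0, Â⁻¹); returns shape (K, n)."""
    A = 0.5 * (A_hat + A_hat.T)
    L = np.linalg.cholesky(np.linalg.inv(A))
    return L @ rng.standard_normal((A.shape[0], n))


def sample(
    params: ModelParams,
    config: FitConfig,
    rng: np.random.Generator,
    ops: Operators = None,
    add_noise: bool = False,
    z: np.ndarray = None,
):
    """Draw z ~ N(0, Â⁻¹), reconstruct, shoot and warp.

    Returns (expected image in subject space, z).  With ``add_noise`` the
    noise model's sampling is applied on top (Gaussian additive noise,
    Bernoulli / categorical draws).
    """
    ops = ops or Operators.from_config(params.grid, config)
    if z is None:
        z = sample_latents(params.A_hat, 1, rng)[:, 0]
    a, v = reconstruct(params, z)
    defm = geodesic_shoot(v, ops.Lv, config.n_shoot_steps)
    ap = pull(a, defm)
    img = lk.expected_image(ap, params.noise)
    if add_noise:
        if params.noise == lk.GAUSSIAN:
            img = img + np.sqrt(params.sigma2) * rng.standard_normal(img.shape)
        elif params.noise == lk.BERNOULLI:
            img = (rng.random(img.shape) < img).astype(float)
        else:
            flat = img.reshape(-1, img.shape[-1])
            draws = np.array([rng.multinomial(1, p / p.sum()) for p in flat])
            img = draws.reshape(img.shape).astype(float)
    return img, z


def heldout_loglik(
    truth: np.ndarray, prediction: np.ndarray, noise: str, sigma2: float = None,
    mask: np.ndarray = None, eps: float = 1e-6,
):
    """Mean per-voxel predictive log-likelihood of ``truth`` under the
    model's expected image, over ``mask`` (natural log)."""
    if mask is None:
        mask = (
            np.all(np.isfinite(truth), axis=-1)
            if noise == lk.CATEGORICAL
            else np.isfinite(truth)
        )
    if mask.sum() == 0:
        return np.nan
    if noise == lk.GAUSSIAN:
        r = truth[mask] - prediction[mask]
        ll = -0.5 * (np.log(2 * np.pi * sigma2) + r**2 / sigma2)
        return float(ll.mean())
    if noise == lk.BERNOULLI:
        p = np.clip(prediction[mask], eps, 1 - eps)
        t = truth[mask]
        return float(np.mean(t * np.log(p) + (1 - t) * np.log1p(-p)))
    p = np.clip(prediction[mask, :], eps, 1.0)
    p = p / p.sum(axis=-1, keepdims=True)
    t = truth[mask, :]
    return float(np.mean(np.sum(t * np.log(p), axis=-1)))


def impute(
    f: lk.ObservedImage,
    params: ModelParams,
    config: FitConfig,
    ops: Operators = None,
    n_iter: int = 12,
    truth: np.ndarray = None,
):
    """Encode from observed voxels only; return the full expected image.

    Returns (imputed image, Encoding, heldout score or None).  When
    ``truth`` is given, voxels missing in ``f`` but finite in ``truth`` are
    scored by mean predictive log-likelihood.
    """
    ops = ops or Operators.from_config(params.grid, config)
    enc = encode(f, params, config, ops=ops, n_iter=n_iter)
    a, v = reconstruct(params, enc.z_hat)
    defm = geodesic_shoot(v, ops.Lv, config.n_shoot_steps)
    pred = lk.expected_image(pull(a, defm), params.noise)
    score = None
    if truth is not None:
        if params.noise == lk.CATEGORICAL:
            held = ~f.mask & np.all(np.isfinite(truth), axis=-1)
        else:
            held = ~f.mask & np.isfinite(truth)
        score = heldout_loglik(truth, pred, params.noise, params.sigma2, held)
    return pred, enc, score


def overlap_metrics(mean_mask: np.ndarray, binary_mask: np.ndarray, eps: float = 1e-6):
    """Jaccard of the thresholded mean versus a binary mask, and the mean
    per-voxel binomial log2-likelihood of the mask under the mean."""
    mu = np.asarray(mean_mask, dtype=float)
    b = np.asarray(binary_mask, dtype=float)
    if mu.shape != b.shape:
        raise ValueError("masks must share one lattice")
    mu_thr = mu > 0.5
    bb = b > 0.5
    union = np.logical_or(mu_thr, bb).sum()
    inter = np.logical_and(mu_thr, bb).sum()
    jaccard = float(inter / union) if union > 0 else 1.0
    muc = np.clip(mu, eps, 1 - eps)
    loglik = float(np.mean(b * np.log2(muc) + (1 - b) * np.log2(1 - muc)))
    return jaccard, loglik


def cross_validate_configs(images, configs, rng, mask_fraction: float = 0.25,
                           noise: str = None, n_encode_iter: int = 12):
    """Compare model configurations by held-out imputation accuracy.

    A random wrapped rectangle covering ``mask_fraction`` of each image is
    set to NaN; each named configuration in ``configs`` (list of
    (name, FitConfig)) is fitted to the masked data and scored by the mean
    predictive log-likelihood of the hidden voxels.  Returns a dict
    name → {"per_image": array, "mean": float}.
    """
    from .model import ShapeAppearanceModel
    from .synth import apply_missing_rectangles

    images = [np.asarray(im, dtype=float) for im in images]
    noise = noise or configs[0][1].noise
    masked, masks = apply_missing_rectangles(images, mask_fraction, rng, noise)
    table = {}
    for name, cfg in configs:
        res = ShapeAppearanceModel(
            [lk.ObservedImage(m, noise) for m in masked], cfg
        ).fit()
        scores = np.empty(len(images))
        for n, (orig, m) in enumerate(zip(images, masked)):
            obs = lk.ObservedImage(m, noise)
            _, _, score = impute(
                obs, res.params, cfg, ops=res.model.ops,
                n_iter=n_encode_iter, truth=orig,
            )
            scores[n] = score
        table[name] = {"per_image": scores, "mean": float(np.nanmean(scores))}
    return table
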