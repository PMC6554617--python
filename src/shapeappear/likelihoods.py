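"""Noise-model energies with template-space gradients and Hessians.

Each image f_n is compared with its warped reconstruction a′ = pull(a, ψ)
under one of three observation models — Gaussian, Bernoulli (logistic) or
categorical (softmax) — giving an energy J = −log p(f | a′) summed over
observed voxels.  Missing voxels (NaN in the data) are simply ignored: they
contribute nothing to the energy, gradient or Hessian.

Gradients and Hessians are returned already pushed to template space through
the adjoint Ψᵀ, which is where every Gauss-Newton consumer needs them.  The
Hessians use the row-sum diagonal majoriser diag(Ψᵀ d): because interpolation
weights are non-negative and rows of Ψ sum to one, diag(Ψᵀd) − Ψᵀ diag(d) Ψ
is positive semi-definite, so the majorised Gauss-Newton steps remain descent
directions under the backtracking line search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffeo import Deformation, pull, push

GAUSSIAN = "gaussian"
BERNOULLI = "bernoulli"
CATEGORICAL = "categorical"
NOISE_MODELS = (GAUSSIAN, BERNOULLI, CATEGORICAL)


@dataclass
class ObservedImage:
    """Lattice data with missing-voxel mask and noise-model tag.

    ``data`` is (*dims,) for gaussian/bernoulli or (*dims, C) for
    categorical.  Missingness is encoded as NaN; the mask is derived (a
    categorical voxel is observed only if all channels are finite).
    """

    data: np.ndarray
    model: str
    mask: np.ndarray = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.model == CATEGORICAL:
            if self.data.ndim < 3:
                raise ValueError("categorical data needs a trailing channel axis")
            self.mask = np.all(np.isfinite(self.data), axis=-1)
        else:
            self.mask = np.isfinite(self.data)
        obs = self.data[self.mask] if self.model != CATEGORICAL else self.data[self.mask, :]
        if self.model == BERNOULLI and obs.size:
            if obs.min() < -1e-6 or obs.max() > 1 + 1e-6:
                raise ValueError("bernoulli data must lie in [0, 1] where observed")
        if self.model == CATEGORICAL and obs.size:
            if obs.min() < -1e-6 or obs.max() > 1 + 1e-6:
                raise ValueError("categorical channels must lie in [0, 1]")
            if obs.sum(axis=-1).max() > 1 + 1e-6:
                raise ValueError("categorical channel sums must be <= 1")

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    @property
    def n_channels(self) -> int:
        return self.data.shape[-1] if self.model == CATEGORICAL else 1


@dataclass
class EnergyDerivs:
    """Energy with template-space gradient and majorised Hessian diagonal."""

    energy: float
    grad: np.ndarray
    hess: np.ndarray


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _softmax(a):
    amax = a.max(axis=-1, keepdims=True)
    e = np.exp(a - amax)
    return e / e.sum(axis=-1, keepdims=True)


def gaussian_derivs(
    f: ObservedImage, a: np.ndarray, deformation: Deformation, sigma2: float
) -> EnergyDerivs:
    """Stationary Gaussian noise: J = ½σ⁻²‖f − a′‖² + (M_obs/2)(ln σ² + ln 2π)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    ap = pull(a, deformation)
    mask = f.mask
    r = np.where(mask, ap - f.data, 0.0)
    r = np.where(np.isfinite(r), r, 0.0)
    m_obs = f.n_observed
    energy = 0.5 / sigma2 * float(np.sum(r * r)) + 0.5 * m_obs * (
        np.log(sigma2) + np.log(2.0 * np.pi)
    )
    grad = push(r / sigma2, deformation)
    hess = push(mask.astype(float) / sigma2, deformation)
    return EnergyDerivs(energy, grad, hess)


def bernoulli_derivs(
    f: ObservedImage, a: np.ndarray, deformation: Deformation
) -> EnergyDerivs:
    """Bernoulli noise through a logistic sigmoid: J = Σ softplus(a′) − f·a′."""
    ap = pull(a, deformation)
    mask = f.mask & np.isfinite(ap)
    apm = np.where(mask, ap, 0.0)
    fm = np.where(mask, f.data, 0.0)
    energy = float(np.sum(np.where(mask, np.logaddexp(0.0, apm) - fm * apm, 0.0)))
    s = _sigmoid(apm)
    grad = push(np.where(mask, s - fm, 0.0), deformation)
    hess = push(np.where(mask, s * (1.0 - s), 0.0), deformation)
    return EnergyDerivs(energy, grad, hess)


def categorical_derivs(
    f: ObservedImage, a: np.ndarray, deformation: Deformation
) -> EnergyDerivs:
    """Categorical noise through a max-stabilised softmax.

    The Hessian is the per-voxel C×C matrix s(δ − s), pushed class-pair-wise
    through the row-sum majoriser, so the returned field has shape
    (*dims, C, C) and stays PSD.
    """
    ap = pull(a, deformation)
    mask = f.mask & np.all(np.isfinite(ap), axis=-1)
    apm = np.where(mask[..., None], ap, 0.0)
    fm = np.where(mask[..., None], f.data, 0.0)
    amax = apm.max(axis=-1)
    lse = amax + np.log(np.sum(np.exp(apm - amax[..., None]), axis=-1))
    energy = float(np.sum(np.where(mask, lse - np.sum(fm * apm, axis=-1), 0.0)))
    s = _softmax(apm)
    grad = push(np.where(mask[..., None], s - fm, 0.0), deformation)
    C = ap.shape[-1]
    Hvox = s[..., :, None] * (np.eye(C) - s[..., None, :])
    Hvox = 0.5 * (Hvox + np.swapaxes(Hvox, -1, -2))
    Hvox = np.where(mask[..., None, None], Hvox, 0.0)
    hess = np.empty_like(Hvox)
    for c in range(C):
        for j in range(c, C):
            pushed = push(Hvox[..., c, j], deformation)
            hess[..., c, j] = pushed
            hess[..., j, c] = pushed
    return EnergyDerivs(energy, grad, hess)


def energy_derivs(
    f: ObservedImage, a: np.ndarray, deformation: Deformation, sigma2: float = None
) -> EnergyDerivs:
    """Dispatch on the image's noise-model tag."""
    if f.model == GAUSSIAN:
        return gaussian_derivs(f, a, deformation, sigma2)
    if f.model == BERNOULLI:
        return bernoulli_derivs(f, a, deformation)
    return categorical_derivs(f, a, deformation)


def energy_only(
    f: ObservedImage, a: np.ndarray, deformation: Deformation, sigma2: float = None
) -> float:
    """Energy J without derivative work (used by line searches)."""
    ap = pull(a, deformation)
    if f.model == GAUSSIAN:
        mask = f.mask
        r = np.where(mask, ap - f.data, 0.0)
        r = np.where(np.isfinite(r), r, 0.0)
        return 0.5 / sigma2 * float(np.sum(r * r)) + 0.5 * f.n_observed * (
            np.log(sigma2) + np.log(2.0 * np.pi)
        )
    if f.model == BERNOULLI:
        mask = f.mask & np.isfinite(ap)
        apm = np.where(mask, ap, 0.0)
        fm = np.where(mask, f.data, 0.0)
        return float(np.sum(np.where(mask, np.logaddexp(0.0, apm) - fm * apm, 0.0)))
    mask = f.mask & np.all(np.isfinite(ap), axis=-1)
    apm = np.where(mask[..., None], ap, 0.0)
    fm = np.where(mask[..., None], f.data, 0.0)
    amax = apm.max(axis=-1)
    lse = amax + np.log(np.sum(np.exp(apm - amax[..., None]), axis=-1))
    return float(np.sum(np.where(mask, lse - np.sum(fm * apm, axis=-1), 0.0)))


def expected_image(a_warped: np.ndarray, model: str) -> np.ndarray:
    """E[f | a′] under the noise model (identity / sigmoid / softmax)."""
    if model == GAUSSIAN:
        return a_warped
    if model == BERNOULLI:
        return _sigmoid(a_warped)
    return _softmax(a_warped)


def update_sigma2(sum_sq_residual: float, n_observed: int, floor: float = 1e-12) -> float:
    """Maximum-likelihood σ² = Σ‖f − a′‖² / M_obs, floored away from zero."""
    if n_observed <= 0:
        return max(floor, 1e-12)
    return max(float(sum_sq_residual) / float(n_observed), floor)
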