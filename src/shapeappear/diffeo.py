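"""Diffeomorphic deformations by geodesic shooting, with pull/push resampling.

A deformation ψ is represented by the coordinates it samples from, in voxel
units, on the same periodic lattice as the images.  ``geodesic_shoot``
integrates the EPDiff momentum-conservation equations with explicit Euler
steps: the initial momentum u0 = L v is transported by the evolving map as
u(t) = |Dψ| (Dψ)ᵀ (u0 ∘ ψ), the velocity is recovered through the Green's
function v(t) = L⁻¹ u(t), and the map is composed with a small displacement
each step.  ``pull`` resamples an image along ψ with multilinear periodic
interpolation; ``push`` is its exact adjoint (splatting with identical
weights), which is what moves likelihood gradients from subject space back
to template space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .operators import GridSpec, LinearOperator


@dataclass
class Deformation:
    """A sampled map ψ on the lattice (voxel units, periodic).

    ``map`` has shape (*dims, d): ``map[x]`` is the (template-space)
    coordinate image values are interpolated from at output voxel x.
    """

    grid: GridSpec
    map: np.ndarray
    jac_det: np.ndarray = None
    folded: bool = False  # set when min |Dψ| <= 0 was detected

    @property
    def displacement(self) -> np.ndarray:
        return self.map - identity_map(self.grid)


def identity_map(grid: GridSpec) -> np.ndarray:
    """The identity coordinate field, shape (*dims, d)."""
    axes = [np.arange(n, dtype=float) for n in grid.dims]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def identity_deformation(grid: GridSpec) -> Deformation:
    return Deformation(grid, identity_map(grid), np.ones(grid.dims))


def _corner_weights(coords, dims):
    """Shared interpolation machinery for pull and push.

    Yields (index_tuple, weight) for each of the 2^d corners of the
    multilinear interpolation at ``coords`` (shape (*out, d)), with periodic
    wrapping.  Weights are non-negative and sum to 1 per output voxel.
    """
    d = coords.shape[-1]
    floor = np.floor(coords)
    frac = coords - floor
    base = floor.astype(np.int64)
    for offs in itertools.product((0, 1), repeat=d):
        w = np.ones(coords.shape[:-1])
        idx = []
        for ax, o in enumerate(offs):
            w = w * (frac[..., ax] if o else 1.0 - frac[..., ax])
            idx.append(np.mod(base[..., ax] + o, dims[ax]))
        yield tuple(idx), w


def pull(image: np.ndarray, deformation: Deformation) -> np.ndarray:
    """Resample ``image`` at ψ(x): out(x) = Σ_y Ψ[x,y] image(y).

    Multilinear, periodic; linear in the image; rows of the implicit sparse
    matrix Ψ sum to 1.  NaN propagates conservatively: any output voxel with
    positive weight on a NaN source voxel becomes NaN.  Corners with exactly
    zero weight contribute nothing, so an identity deformation reproduces
    the input bit-exactly.
    """
    image = np.asarray(image, dtype=float)
    grid = deformation.grid
    d = grid.ndim
    if image.shape[:d] != grid.dims:
        raise ValueError(f"image shape {image.shape} does not match grid {grid.dims}")
    out = np.zeros_like(image)
    for idx, w in _corner_weights(deformation.map, grid.dims):
        vals = image[idx]
        if image.ndim > d:
            w = w[..., None]
        # 0 * NaN would poison zero-weight corners; mask them out explicitly
        contrib = np.where(w > 0, w * vals, 0.0)
        nan_touch = (w > 0) & ~np.isfinite(np.where(w > 0, vals, 0.0))
        out = out + contrib
        out[nan_touch] = np.nan
    return out


def push(image: np.ndarray, deformation: Deformation) -> np.ndarray:
    """Exact adjoint of :func:`pull` (splatting with the same weights).

    ⟨pull(a, ψ), f⟩ = ⟨a, push(f, ψ)⟩ for all a, f.  NaN source voxels
    contribute nothing (their weights are dropped), so pushing a residual
    with missing entries zeroed is safe.
    """
    image = np.asarray(image, dtype=float)
    grid = deformation.grid
    d = grid.ndim
    if image.shape[:d] != grid.dims:
        raise ValueError(f"image shape {image.shape} does not match grid {grid.dims}")
    out = np.zeros_like(image)
    finite = np.isfinite(image)
    src = np.where(finite, image, 0.0)
    for idx, w in _corner_weights(deformation.map, grid.dims):
        if image.ndim > d:
            w = w[..., None]
        np.add.at(out, idx, w * src)
    return out


def _jacobian(disp: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Jacobian of ψ = id + disp by central differences, periodic.

    Returns shape (*dims, d, d) with J[..., i, j] = ∂ψ_i/∂x_j.
    """
    d = grid.ndim
    J = np.empty(grid.dims + (d, d))
    for j in range(d):
        dj = 0.5 * (np.roll(disp, -1, axis=j) - np.roll(disp, 1, axis=j))
        for i in range(d):
            J[..., i, j] = dj[..., i]
        J[..., j, j] += 1.0
    return J


def jacobian_determinant(deformation: Deformation) -> np.ndarray:
    """Per-voxel |Dψ| from central differences of the displacement."""
    J = _jacobian(deformation.displacement, deformation.grid)
    return np.linalg.det(J)


def geodesic_shoot(
    v: np.ndarray, op: LinearOperator, n_steps: int = 8
) -> Deformation:
    """Integrate the geodesic from initial velocity ``v`` (shape (*dims, d)).

    Explicit Euler with momentum conservation: each step composes
    ψ ← ψ∘(id − h v_t), recomputes the Jacobian, transports
    u_t = |Dψ|(Dψ)ᵀ(u0∘ψ) and recovers v_t = L⁻¹ u_t.  Spatially constant
    velocities are exact geodesics (ψ(x) = x − t·v).  Returns a Deformation
    with ``jac_det`` populated; a non-positive Jacobian determinant sets the
    ``folded`` flag rather than raising.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if op.kind != "velocity":
        raise ValueError("geodesic shooting needs a velocity-kind operator")
    grid = op.grid
    d = grid.ndim
    v = np.asarray(v, dtype=float)
    if v.shape != grid.dims + (d,):
        raise ValueError(f"velocity must have shape {grid.dims + (d,)}")
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite initial velocity")

    u0 = op.apply(v)
    h = 1.0 / n_steps
    disp = np.zeros_like(v)  # ψ − id
    vt = v
    ident = identity_map(grid)
    for step in range(n_steps):
        # compose ψ ← ψ ∘ (id − h v_t): new_disp(x) = disp(x − h v_t(x)) − h v_t(x)
        small = Deformation(grid, ident - h * vt)
        disp = pull(disp, small) - h * vt
        if not np.all(np.isfinite(disp)):
            raise FloatingPointError(f"non-finite deformation at Euler step {step + 1}")
        if step == n_steps - 1:
            break
        J = _jacobian(disp, grid)
        det = np.linalg.det(J)
        psi = Deformation(grid, ident + disp)
        u_pulled = pull(u0, psi)
        ut = det[..., None] * np.einsum("...ji,...j->...i", J, u_pulled)
        vt = op.apply_inverse(ut)
        if not np.all(np.isfinite(vt)):
            raise FloatingPointError(f"non-finite velocity at Euler step {step + 1}")

    result = Deformation(grid, ident + disp)
    result.jac_det = jacobian_determinant(result)
    if result.jac_det.min() <= 0:
        result.folded = True
    return result
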