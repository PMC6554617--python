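"""Sobolev regularisation operators on periodic lattices.

The shape and appearance priors are zero-mean Gaussians whose precisions are
discretised differential operators: a five-term operator ``L^v`` acting on
vector (velocity) fields — absolute displacement, membrane, bending,
linear-elastic and divergence penalties — and a three-term operator ``L^a`` /
``L^mu`` acting on scalar images.  With periodic boundary conditions every
penalty is a convolution, so the whole operator diagonalises over discrete
frequencies into small d×d Hermitian transfer matrices.  Forward application
(field → momentum), inverse application (the Green's function used by
geodesic shooting) and regularised Gauss-Newton solves all live here.

Discretisation: first-order terms use forward differences (adjoint pairs
``(u[x+e]-u[x])/h``), bending uses the squared discrete Laplacian
``[1,-2,1]/h²`` per axis, and the quadratic form carries the voxel-volume
measure.  Constants (and rigid translations, for the vector operator) are in
the null space whenever ``w0 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """A regular 2D or 3D image lattice.

    Parameters
    ----------
    dims : tuple of int
        Voxel counts per axis; each must be >= 4.
    voxel_size : tuple of float
        Spacing per axis in mm; defaults to 1 mm isotropic.
    """

    dims: tuple
    voxel_size: tuple = None

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        if len(dims) not in (2, 3):
            raise ValueError(f"grid must be 2D or 3D, got {len(dims)} axes")
        if any(d < 4 for d in dims):
            raise ValueError(f"all dims must be >= 4, got {dims}")
        vs = self.voxel_size
        if vs is None:
            vs = (1.0,) * len(dims)
        vs = tuple(float(v) for v in vs)
        if len(vs) != len(dims):
            raise ValueError("voxel_size length must match dims")
        if any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be positive, got {vs}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "voxel_size", vs)

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass(frozen=True)
class VelRegWeights:
    """Penalty weights for the velocity operator.

    w0 absolute displacement, w1 membrane (stretch/shear/rotation),
    w2 bending, w3 linear elastic (symmetrised Jacobian), w4 divergence.
    """

    w0: float = 1e-6
    w1: float = 0.0
    w2: float = 0.0
    w3: float = 0.0
    w4: float = 0.0

    def __post_init__(self):
        ws = self.as_tuple()
        if any(w < 0 for w in ws):
            raise ValueError(f"weights must be non-negative, got {ws}")
        if all(w == 0 for w in ws):
            raise ValueError("at least one weight must be positive")

    def as_tuple(self):
        return (self.w0, self.w1, self.w2, self.w3, self.w4)


@dataclass(frozen=True)
class ScalarRegWeights:
    """Penalty weights for the scalar (appearance / template) operator.

    w0 absolute value, w1 membrane, w2 bending.
    """

    w0: float = 1e-6
    w1: float = 0.0
    w2: float = 0.0

    def __post_init__(self):
        ws = self.as_tuple()
        if any(w < 0 for w in ws):
            raise ValueError(f"weights must be non-negative, got {ws}")
        if all(w == 0 for w in ws):
            raise ValueError("at least one weight must be positive")

    def as_tuple(self):
        return (self.w0, self.w1, self.w2)


def _freq_symbols(grid: GridSpec):
    """Forward-difference symbols c_i(k) = (e^{iθ_i}-1)/h_i on the full grid.

    Returns (c, s) where c has shape (*dims, d) complex and s = |c|² real.
    """
    d = grid.ndim
    axes = []
    for i, (n, h) in enumerate(zip(grid.dims, grid.voxel_size)):
        theta = 2.0 * np.pi * np.fft.fftfreq(n)
        axes.append((np.exp(1j * theta) - 1.0) / h)
    mesh = np.meshgrid(*axes, indexing="ij")
    c = np.stack(mesh, axis=-1)
    s = (c * c.conj()).real
    return c, s


class LinearOperator:
    """A self-adjoint PSD Sobolev precision operator, diagonal in frequency.

    ``kind`` is "velocity" (acts on (*dims, d) fields through d×d transfer
    matrices) or "scalar" (acts on (*dims,) or (*dims, C) fields through a
    real scalar spectrum).  Strictly positive definite iff ``w0 > 0``.
    """

    def __init__(self, grid: GridSpec, kind: str, weights):
        if kind not in ("velocity", "scalar"):
            raise ValueError(f"unknown operator kind {kind!r}")
        self.grid = grid
        self.kind = kind
        self.weights = weights
        vol = grid.voxel_volume
        c, s = _freq_symbols(grid)
        lam = s.sum(axis=-1)  # discrete Laplacian magnitude Σ|c_i|²
        if kind == "scalar":
            w0, w1, w2 = weights.as_tuple()
            self.spectrum = vol * (w0 + w1 * lam + w2 * lam**2)
            self._inv_spectrum = None
        else:
            w0, w1, w2, w3, w4 = weights.as_tuple()
            d = grid.ndim
            alpha = vol * (w0 + (w1 + 0.5 * w3) * lam + w2 * lam**2)
            A = np.zeros(grid.dims + (d, d), dtype=complex)
            idx = np.arange(d)
            A[..., idx, idx] = alpha[..., None]
            # rank-1 couplings: (w3/2)·c c^H (elastic) + w4·conj(c) c^T (div)
            A += vol * 0.5 * w3 * (c[..., :, None] * c[..., None, :].conj())
            A += vol * w4 * (c[..., :, None].conj() * c[..., None, :])
            self.transfer = A
            self._inv_transfer = None

    # -- diagnostics ------------------------------------------------------
    def is_strictly_pd(self, tol: float = 0.0) -> bool:
        if self.kind == "scalar":
            return bool(self.spectrum.min() > tol)
        eig = np.linalg.eigvalsh(self.transfer)
        return bool(eig.min() > tol)

    # -- forward ----------------------------------------------------------
    def apply(self, field: np.ndarray) -> np.ndarray:
        """Momentum u = L field (shape-preserving)."""
        field = np.asarray(field, dtype=float)
        d = self.grid.ndim
        if self.kind == "scalar":
            if field.shape[:d] != self.grid.dims:
                raise ValueError(
                    f"field shape {field.shape} does not match grid {self.grid.dims}"
                )
            F = np.fft.fftn(field, axes=tuple(range(d)))
            spec = self.spectrum
            if field.ndim > d:  # trailing channel axis
                spec = spec.reshape(spec.shape + (1,) * (field.ndim - d))
            return np.fft.ifftn(spec * F, axes=tuple(range(d))).real
        if field.shape != self.grid.dims + (d,):
            raise ValueError(
                f"velocity field must have shape {self.grid.dims + (d,)}, got {field.shape}"
            )
        F = np.fft.fftn(field, axes=tuple(range(d)))
        out = np.einsum("...ij,...j->...i", self.transfer, F)
        return np.fft.ifftn(out, axes=tuple(range(d))).real

    # -- inverse (Green's function) ---------------------------------------
    def apply_inverse(self, momentum: np.ndarray) -> np.ndarray:
        """Green's-function deconvolution: returns v with L v = momentum.

        Requires a strictly positive definite operator (w0 > 0).
        """
        momentum = np.asarray(momentum, dtype=float)
        d = self.grid.ndim
        if self.kind == "scalar":
            if self._inv_spectrum is None:
                if self.spectrum.min() <= 0:
                    raise np.linalg.LinAlgError(
                        "singular scalar operator (w0 = 0); no strict inverse"
                    )
                self._inv_spectrum = 1.0 / self.spectrum
            F = np.fft.fftn(momentum, axes=tuple(range(d)))
            spec = self._inv_spectrum
            if momentum.ndim > d:
                spec = spec.reshape(spec.shape + (1,) * (momentum.ndim - d))
            return np.fft.ifftn(spec * F, axes=tuple(range(d))).real
        if self._inv_transfer is None:
            det = np.linalg.det(self.transfer)
            if np.abs(det).min() <= 0:
                raise np.linalg.LinAlgError(
                    "singular velocity operator (w0 = 0); no strict inverse"
                )
            self._inv_transfer = np.linalg.inv(self.transfer)
        F = np.fft.fftn(momentum, axes=tuple(range(d)))
        out = np.einsum("...ij,...j->...i", self._inv_transfer, F)
        return np.fft.ifftn(out, axes=tuple(range(d))).real

    def quad_form(self, field: np.ndarray) -> float:
        """⟨field, L field⟩ — the discretised Sobolev energy (≥ 0)."""
        u = np.asarray(field, dtype=float)
        return float(np.sum(u * self.apply(u)))

    def gram(self, columns) -> np.ndarray:
        """Gram matrix [⟨w_k, L w_l⟩] of a list of fields."""
        K = len(columns)
        Lw = [self.apply(w) for w in columns]
        G = np.empty((K, K))
        for k in range(K):
            for l in range(k, K):
                G[k, l] = G[l, k] = float(np.sum(columns[k] * Lw[l]))
        return G


def build_velocity_operator(grid: GridSpec, weights: VelRegWeights) -> LinearOperator:
    """Discretise the five-term velocity precision on a periodic lattice."""
    return LinearOperator(grid, "velocity", weights)


def build_scalar_operator(grid: GridSpec, weights: ScalarRegWeights) -> LinearOperator:
    """Discretise the three-term scalar precision on a periodic lattice."""
    return LinearOperator(grid, "scalar", weights)


def apply(op: LinearOperator, field: np.ndarray) -> np.ndarray:
    return op.apply(field)


def apply_inverse(op: LinearOperator, momentum: np.ndarray) -> np.ndarray:
    return op.apply_inverse(momentum)


def quad_form(op: LinearOperator, field: np.ndarray) -> float:
    return op.quad_form(field)


class SolveError(RuntimeError):
    """PCG failed to reach tolerance; carries the final relative residual."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"regularised solve did not converge: rel. residual {residual:.3e} "
            f"after {iterations} iterations"
        )


def _apply_hfield(h_field, x, d_spatial):
    """Apply a per-voxel diagonal or small-matrix Hessian field to x."""
    if h_field is None:
        return np.zeros_like(x)
    h = np.asarray(h_field, dtype=float)
    if h.shape == x.shape[:d_spatial]:  # scalar diagonal
        if x.ndim > d_spatial:
            return h.reshape(h.shape + (1,) * (x.ndim - d_spatial)) * x
        return h * x
    if h.shape == x.shape:  # per-channel diagonal
        return h * x
    if h.shape == x.shape + (x.shape[-1],):  # per-voxel small matrix
        return np.einsum("...ij,...j->...i", h, x)
    raise ValueError(f"Hessian field shape {h.shape} incompatible with {x.shape}")


def solve_regularized(
    h_field,
    op: LinearOperator,
    g_field: np.ndarray,
    tol: float = 1e-6,
    maxiter: int = 500,
    raise_on_fail: bool = True,
):
    """Solve (H + L) x = g by preconditioned conjugate gradients.

    ``h_field`` is a per-voxel non-negative diagonal (same spatial shape as
    ``g_field``, optionally per channel) or a per-voxel symmetric PSD matrix
    field with one extra trailing axis.  The preconditioner is the spectral
    inverse of L shifted by the mean diagonal of H, which makes the Green's
    function the exact solve when H is spatially constant.

    Returns ``(x, rel_residual)``.
    """
    g = np.asarray(g_field, dtype=float)
    d = op.grid.ndim

    if h_field is None:
        hbar = 0.0
    else:
        h = np.asarray(h_field, dtype=float)
        if g.ndim > d and h.shape == g.shape + (g.shape[-1],):
            hbar = float(np.einsum("...ii->...", h).mean() / g.shape[-1])
        else:
            hbar = float(h.mean())

    vol = op.grid.voxel_volume
    if op.kind == "scalar":
        pre_spec = 1.0 / (op.spectrum + max(hbar, 1e-12 * vol))

        def precond(r):
            F = np.fft.fftn(r, axes=tuple(range(d)))
            spec = pre_spec
            if r.ndim > d:
                spec = spec.reshape(spec.shape + (1,) * (r.ndim - d))
            return np.fft.ifftn(spec * F, axes=tuple(range(d))).real

    else:
        dd = op.grid.ndim
        shift = np.zeros(op.transfer.shape, dtype=complex)
        idx = np.arange(dd)
        shift[..., idx, idx] = max(hbar, 1e-12 * vol)
        pre_inv = np.linalg.inv(op.transfer + shift)

        def precond(r):
            F = np.fft.fftn(r, axes=tuple(range(d)))
            out = np.einsum("...ij,...j->...i", pre_inv, F)
            return np.fft.ifftn(out, axes=tuple(range(d))).real

    def matvec(x):
        return _apply_hfield(h_field, x, d) + op.apply(x)

    x = np.zeros_like(g)
    r = g.copy()
    gnorm = float(np.linalg.norm(g))
    if gnorm == 0.0:
        return x, 0.0
    z = precond(r)
    p = z.copy()
    rz = float(np.sum(r * z))
    rel = 1.0
    for it in range(1, maxiter + 1):
        Ap = matvec(p)
        pAp = float(np.sum(p * Ap))
        if pAp <= 0:
            break  # numerically indefinite direction; stop with best iterate
        alpha = rz / pAp
        x = x + alpha * p
        r = r - alpha * Ap
        rel = float(np.linalg.norm(r)) / gnorm
        if rel < tol:
            return x, rel
        z = precond(r)
        rz_new = float(np.sum(r * z))
        p = z + (rz_new / rz) * p
        rz = rz_new
    if raise_on_fail and rel >= tol:
        raise SolveError(rel, maxiter)
    return x, rel
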