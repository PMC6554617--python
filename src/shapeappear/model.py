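"""Joint shape-and-appearance factor model and its fitting algorithm.

Each image f_n is generated from K latent variables z_n through two linear
bases: an appearance reconstruction a_n = μ + W^a z_n perturbing the mean
template, and an initial velocity v_n = W^v z_n whose geodesic shooting
yields a diffeomorphism ψ_n; the model prediction is pull(a_n, ψ_n) observed
under a Gaussian, Bernoulli or categorical noise model.  Latents carry a
zero-mean Gaussian prior whose precision A is given a Wishart prior and
inferred variationally; basis columns carry Sobolev smoothness priors.

Fitting alternates single Gauss-Newton updates of μ, W^a and W^v (each
safeguarded by a backtracking line search on the joint log-probability),
re-orthogonalisation of the latent rows, Gauss-Newton updates of each z_n
with Laplace covariances, and the closed-form Wishart expectation update.
The public surface is statsmodels-style: build a
:class:`ShapeAppearanceModel` from data and call ``fit()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import likelihoods as lk
from .diffeo import geodesic_shoot, pull
from .operators import (
    GridSpec,
    LinearOperator,
    ScalarRegWeights,
    VelRegWeights,
    build_scalar_operator,
    build_velocity_operator,
    solve_regularized,
)

SHARED = "shared"
SPLIT = "split"


@dataclass
class FitConfig:
    """Settings for model structure, regularisation and optimisation.

    K is the number of latent variables.  In split mode K = Ka + Kv and the
    first Ka latents drive appearance only, the rest shape only; in shared
    mode every latent drives both and Ka = Kv = K.
    """

    K: int = 8
    mode: str = SHARED
    Ka: int = None  # split mode only
    Kv: int = None
    noise: str = lk.GAUSSIAN
    lambda1: float = 0.9
    lambda2: float = 0.1
    n_iter: int = 8
    n_shoot_steps: int = 8
    n_latent_iter: int = 3
    omega_v: tuple = (1e-3, 0.0, 4.0, 0.25, 0.5)
    omega_a: tuple = (1e-3, 1.0, 10.0)
    omega_mu: tuple = (1e-4, 0.01, 0.1)
    nu0: float = None  # defaults to K
    scale_penalty_by_N: bool = True
    seed: int = 0
    sigma2_floor_frac: float = 1e-6  # floor on sigma2, as fraction of data variance
    solve_tol: float = 1e-5
    max_halvings: int = 10

    def __post_init__(self):
        if self.mode not in (SHARED, SPLIT):
            raise ValueError(f"mode must be 'shared' or 'split', got {self.mode!r}")
        if self.mode == SPLIT:
            if self.Ka is None or self.Kv is None:
                raise ValueError("split mode needs explicit Ka and Kv")
            self.Ka, self.Kv = int(self.Ka), int(self.Kv)
            if self.Ka < 0 or self.Kv < 0 or self.Ka + self.Kv < 1:
                raise ValueError("need Ka, Kv >= 0 with Ka + Kv >= 1")
            self.K = self.Ka + self.Kv
        else:
            self.Ka = self.Kv = int(self.K)
        if self.lambda1 + self.lambda2 <= 0:
            raise ValueError("lambda1 + lambda2 must be positive")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.nu0 is None:
            self.nu0 = float(self.K)

    # latent-index bookkeeping -------------------------------------------
    def z_appearance(self, z):
        return z[: self.Ka] if self.mode == SPLIT else z

    def z_shape(self, z):
        return z[self.Ka :] if self.mode == SPLIT else z

    @property
    def appearance_rows(self):
        return np.arange(self.Ka) if self.mode == SPLIT else np.arange(self.K)

    @property
    def shape_rows(self):
        if self.mode == SPLIT:
            return np.arange(self.Ka, self.K)
        return np.arange(self.K)


@dataclass
class ModelParams:
    """Point estimates: template, bases, noise variance, latent precision."""

    grid: GridSpec
    mode: str
    noise: str
    mu: np.ndarray
    Wa: np.ndarray  # (Ka, *image_shape)
    Wv: np.ndarray  # (Kv, *dims, d)
    sigma2: float
    A_hat: np.ndarray  # (K, K)

    @property
    def Ka(self):
        return self.Wa.shape[0]

    @property
    def Kv(self):
        return self.Wv.shape[0]

    @property
    def K(self):
        return self.Ka + self.Kv if self.mode == SPLIT else self.Ka

    def copy(self):
        return ModelParams(
            self.grid,
            self.mode,
            self.noise,
            self.mu.copy(),
            self.Wa.copy(),
            self.Wv.copy(),
            self.sigma2,
            self.A_hat.copy(),
        )


@dataclass
class LatentPosterior:
    """Latent modes with aggregate Laplace uncertainty."""

    Z: np.ndarray  # (K, N)
    S: np.ndarray  # (K, K) sum of per-image Laplace covariances
    Cz: np.ndarray  # (K, K) = Z Zᵀ

    @classmethod
    def from_modes(cls, Z, S=None):
        K = Z.shape[0]
        S = np.zeros((K, K)) if S is None else S
        return cls(Z, S, Z @ Z.T)


@dataclass
class WishartState:
    """Conjugate Wishart posterior over the latent precision A."""

    Lambda0_inv: np.ndarray
    nu0: float
    Lambda: np.ndarray = None
    nu: float = None

    @property
    def K(self):
        return self.Lambda0_inv.shape[0]


@dataclass
class OrthoTransform:
    """The invertible reparameterisation applied at an orthogonalisation."""

    T: np.ndarray  # full K×K transform (already includes the Q scaling)
    Q: np.ndarray  # diagonal positive scaling factors (length K)


@dataclass
class Operators:
    """The three Sobolev operators a configuration induces on a grid."""

    Lv: LinearOperator
    La: LinearOperator
    Lmu: LinearOperator

    @classmethod
    def from_config(cls, grid: GridSpec, config: FitConfig):
        return cls(
            build_velocity_operator(grid, VelRegWeights(*config.omega_v)),
            build_scalar_operator(grid, ScalarRegWeights(*config.omega_a)),
            build_scalar_operator(grid, ScalarRegWeights(*config.omega_mu)),
        )


# ---------------------------------------------------------------------------
# basic operations
# ---------------------------------------------------------------------------


def init_latents(N: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random Z (K×N) with exactly orthogonal rows: Z Zᵀ = N·I."""
    if N < K:
        raise ValueError(f"cannot draw {K} orthogonal latent rows from N={N} images")
    G = rng.standard_normal((N, K))
    Q, R = np.linalg.qr(G)
    Q = Q * np.sign(np.diag(R))  # fix QR sign ambiguity for determinism
    return np.sqrt(N) * Q.T


def reconstruct(params: ModelParams, z: np.ndarray, config: FitConfig = None):
    """(appearance a = μ + Wᵃ z_a, velocity v = Wᵛ z_v) for one latent code."""
    if params.mode == SPLIT:
        za, zv = z[: params.Ka], z[params.Ka :]
    else:
        za = zv = z
    a = params.mu + np.einsum("k,k...->...", za, params.Wa)
    v = np.einsum("k,k...->...", zv, params.Wv)
    return a, v


def _init_mu(dataset, noise, eps=1e-3):
    """Template init from unaligned data: observed-voxel mean, mapped to the
    noise model's natural (linear / logit / log) scale."""
    stack = np.stack([f.data for f in dataset])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    mean = np.where(np.isfinite(mean), mean, np.nanmean(stack))
    if noise == lk.GAUSSIAN:
        return mean
    mean = np.clip(mean, eps, 1.0 - eps)
    if noise == lk.BERNOULLI:
        return np.log(mean) - np.log1p(-mean)
    return np.log(mean)


def init_model(dataset, config: FitConfig, grid: GridSpec, rng=None):
    """Initial (params, latents, wishart) per the fitting algorithm's recipe:
    μ from the unaligned data, zero bases, random orthogonal latents with
    Cᶻ = N·I, and Â = (N+ν0)(N·I + Λ0⁻¹)⁻¹."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    N = len(dataset)
    K, d = config.K, grid.ndim
    mu = _init_mu(dataset, config.noise)
    Wa = np.zeros((config.Ka,) + mu.shape)
    Wv = np.zeros((config.Kv,) + grid.dims + (d,))
    nu0 = float(config.nu0)
    Lambda0_inv = nu0 * np.eye(K)  # Λ0 = I/ν0
    A_hat = (N + nu0) * np.linalg.inv(N * np.eye(K) + Lambda0_inv)
    A_hat = 0.5 * (A_hat + A_hat.T)

    if config.noise == lk.GAUSSIAN:
        ss, m = 0.0, 0
        for f in dataset:
            r = np.where(f.mask, f.data - mu, 0.0)
            ss += float(np.sum(r * r))
            m += f.n_observed
        sigma2 = max(ss / max(m, 1), 1e-6)
    else:
        sigma2 = 1.0

    params = ModelParams(grid, config.mode, config.noise, mu, Wa, Wv, sigma2, A_hat)
    if N >= K:
        Z = init_latents(N, K, rng)
    else:
        Z = rng.standard_normal((K, N))
    latents = LatentPosterior.from_modes(Z)
    wishart = WishartState(Lambda0_inv, nu0, None, None)
    return params, latents, wishart


def update_precision(latents: LatentPosterior, wishart: WishartState):
    """Variational Wishart update: Λ = (Cᶻ + S + Λ0⁻¹)⁻¹, ν = ν0 + N,
    Â = νΛ (symmetrised)."""
    N = latents.Z.shape[1]
    M = latents.Cz + latents.S + wishart.Lambda0_inv
    M = 0.5 * (M + M.T)
    Lambda = np.linalg.inv(M)
    nu = wishart.nu0 + N
    new = WishartState(wishart.Lambda0_inv, wishart.nu0, 0.5 * (Lambda + Lambda.T), nu)
    A_hat = nu * new.Lambda
    return new, 0.5 * (A_hat + A_hat.T)


def _spatial_gradient(a: np.ndarray, d: int) -> np.ndarray:
    """Central-difference spatial gradient, periodic; output gains a final
    axis of length d.  Matches the symmetric derivative of the multilinear
    interpolant at lattice points."""
    comps = [0.5 * (np.roll(a, -1, axis=ax) - np.roll(a, 1, axis=ax)) for ax in range(d)]
    return np.stack(comps, axis=-1)


def _with_channel(x, noise):
    """View scalar-model fields as single-channel for unified einsums."""
    return x[..., None] if noise != lk.CATEGORICAL else x


# ---------------------------------------------------------------------------
# the fitting engine
# ---------------------------------------------------------------------------


class _Fitter:
    """Holds the mutable optimisation state and per-image caches."""

    def __init__(self, dataset, config: FitConfig, grid: GridSpec, ops=None, rng=None):
        self.dataset = dataset
        self.config = config
        self.grid = grid
        self.N = len(dataset)
        self.d = grid.ndim
        self.ops = ops or Operators.from_config(grid, config)
        self.rng = rng or np.random.default_rng(config.seed)
        self.params, self.latents, self.wishart = init_model(
            dataset, config, grid, self.rng
        )
        self.wishart, self.params.A_hat = self._initial_precision()
        self.defs = [None] * self.N
        self.energies = np.zeros(self.N)
        self.history = []
        self.warnings = []
        data_var = np.nanvar(np.stack([f.data for f in dataset]))
        self.sigma2_floor = max(config.sigma2_floor_frac * data_var, 1e-12)
        self.refresh_all()

    def _initial_precision(self):
        ws = self.wishart
        M = self.latents.Cz + self.latents.S + ws.Lambda0_inv
        Lambda = np.linalg.inv(0.5 * (M + M.T))
        nu = ws.nu0 + self.N
        A = nu * Lambda
        return WishartState(ws.Lambda0_inv, ws.nu0, Lambda, nu), 0.5 * (A + A.T)

    # -- caches -----------------------------------------------------------
    def shoot(self, v):
        return geodesic_shoot(v, self.ops.Lv, self.config.n_shoot_steps)

    def image_state(self, n, mu=None, Wa=None, Wv=None, z=None, defm=None):
        """(a, deformation) for image n under optionally substituted params."""
        p, c = self.params, self.config
        z = self.latents.Z[:, n] if z is None else z
        mu = p.mu if mu is None else mu
        Wa = p.Wa if Wa is None else Wa
        za = z[: c.Ka] if c.mode == SPLIT else z
        a = mu + np.einsum("k,k...->...", za, Wa)
        if defm is None:
            Wv = p.Wv if Wv is None else Wv
            zv = z[c.Ka :] if c.mode == SPLIT else z
            v = np.einsum("k,k...->...", zv, Wv)
            defm = self.shoot(v)
        return a, defm

    def image_energy(self, n, a, defm):
        return lk.energy_only(self.dataset[n], a, defm, self.params.sigma2)

    def refresh_all(self):
        for n in range(self.N):
            a, defm = self.image_state(n)
            self.defs[n] = defm
            self.energies[n] = self.image_energy(n, a, defm)

    # -- objective pieces -------------------------------------------------
    def gram(self, which, Wa=None, Wv=None):
        if which == "a":
            W = self.params.Wa if Wa is None else Wa
            return self.ops.La.gram(list(W))
        W = self.params.Wv if Wv is None else Wv
        return self.ops.Lv.gram(list(W))

    def full_gram(self, Ga=None, Gv=None):
        """K×K combined basis Gram (Wᵃ)ᵀLᵃWᵃ + (Wᵛ)ᵀLᵛWᵛ in latent indices."""
        c = self.config
        Ga = self.gram("a") if Ga is None else Ga
        Gv = self.gram("v") if Gv is None else Gv
        if c.mode == SHARED:
            return Ga + Gv
        G = np.zeros((c.K, c.K))
        G[: c.Ka, : c.Ka] = Ga
        G[c.Ka :, c.Ka :] = Gv
        return G

    def penalty_terms(self, mu=None, Ga=None, Gv=None):
        c = self.config
        mu = self.params.mu if mu is None else mu
        Ga = self.gram("a") if Ga is None else Ga
        Gv = self.gram("v") if Gv is None else Gv
        n_scale = self.N if c.scale_penalty_by_N else 1.0
        pen_mu = 0.5 * self.ops.Lmu.quad_form(mu)
        pen_w = 0.5 * c.lambda1 * n_scale * (np.trace(Ga) + np.trace(Gv))
        Gfull = self.full_gram(Ga, Gv)
        pen_z = 0.5 * c.lambda2 * float(np.sum(self.latents.Cz * Gfull))
        return pen_mu + pen_w + pen_z

    def wishart_term(self):
        c, ws = self.config, self.wishart
        A = self.params.A_hat
        sign, logdet = np.linalg.slogdet(A)
        tr = float(np.sum((self.latents.Cz + ws.Lambda0_inv) * A))
        return 0.5 * c.lambda1 * ((self.N + ws.nu0 - c.K - 1) * logdet - tr)

    def objective(self):
        """The joint log-probability (constants dropped), to be maximised."""
        return float(-self.energies.sum() - self.penalty_terms() + self.wishart_term())

    def log(self, iteration, stage):
        self.history.append(
            {"iter": iteration, "stage": stage, "objective": self.objective()}
        )

    def latent_prior_precision(self):
        c = self.config
        return c.lambda1 * self.params.A_hat + c.lambda2 * self.full_gram()

    # -- stage: mean ------------------------------------------------------
    def update_mean(self):
        p, c = self.params, self.config
        grad = self.ops.Lmu.apply(p.mu)
        hess = None
        for n in range(self.N):
            a, defm = self.image_state(n, defm=self.defs[n])
            dv = lk.energy_derivs(self.dataset[n], a, defm, p.sigma2)
            grad = grad + dv.grad
            hess = dv.hess if hess is None else hess + dv.hess
        step, _ = solve_regularized(
            hess, self.ops.Lmu, grad, tol=c.solve_tol, raise_on_fail=False
        )

        base = -self.energies.sum() - 0.5 * self.ops.Lmu.quad_form(p.mu)
        alpha = 1.0
        for _ in range(c.max_halvings):
            mu_t = p.mu - alpha * step
            en_t = np.empty(self.N)
            for n in range(self.N):
                a_t, defm = self.image_state(n, mu=mu_t, defm=self.defs[n])
                en_t[n] = self.image_energy(n, a_t, defm)
            obj_t = -en_t.sum() - 0.5 * self.ops.Lmu.quad_form(mu_t)
            if obj_t > base:
                p.mu = mu_t
                self.energies = en_t
                return True
            alpha *= 0.5
        self.warnings.append("mean update: line search exhausted, keeping old mu")
        return False

    # -- stage: appearance basis -----------------------------------------
    def update_appearance_basis(self):
        p, c = self.params, self.config
        n_scale = self.N if c.scale_penalty_by_N else 1.0
        rows = c.appearance_rows
        for j, k in enumerate(rows):
            zrow = self.latents.Z[k]
            # gradient/Hessian pass at the current state
            grad = None
            hess = None
            for n in range(self.N):
                if zrow[n] == 0.0:
                    continue
                a, defm = self.image_state(n, defm=self.defs[n])
                dv = lk.energy_derivs(self.dataset[n], a, defm, p.sigma2)
                g = zrow[n] * dv.grad
                h = zrow[n] ** 2 * dv.hess
                grad = g if grad is None else grad + g
                hess = h if hess is None else hess + h
            if grad is None:
                continue  # column unused by every image
            # prior gradient uses the full Cz coupling, Hessian its diagonal
            WCz = np.einsum("l,l...->...", self.latents.Cz[rows][:, k], p.Wa)
            grad = grad + self.ops.La.apply(
                c.lambda1 * n_scale * p.Wa[j] + c.lambda2 * WCz
            )
            reg = c.lambda1 * n_scale + c.lambda2 * self.latents.Cz[k, k]
            step, _ = solve_regularized(
                hess / max(reg, 1e-12),
                self.ops.La,
                grad / max(reg, 1e-12),
                tol=c.solve_tol,
                raise_on_fail=False,
            )
            self._accept_appearance_column(j, step)
        return True

    def _accept_appearance_column(self, j, step):
        p, c = self.params, self.config
        rows = c.appearance_rows
        zrow = self.latents.Z[rows[j]]
        Ga = self.gram("a")
        base = -self.energies.sum() - self._basis_penalty("a", Ga)
        alpha = 1.0
        for _ in range(c.max_halvings):
            Wa_t = p.Wa.copy()
            Wa_t[j] = p.Wa[j] - alpha * step
            en_t = self.energies.copy()
            for n in range(self.N):
                if zrow[n] == 0.0:
                    continue
                a_t, defm = self.image_state(n, Wa=Wa_t, defm=self.defs[n])
                en_t[n] = self.image_energy(n, a_t, defm)
            Ga_t = self.gram("a", Wa=Wa_t)
            obj_t = -en_t.sum() - self._basis_penalty("a", Ga_t)
            if obj_t > base:
                p.Wa = Wa_t
                self.energies = en_t
                return True
            alpha *= 0.5
        self.warnings.append("appearance update: line search exhausted for a column")
        return False

    def _basis_penalty(self, which, G):
        c = self.config
        n_scale = self.N if c.scale_penalty_by_N else 1.0
        rows = c.appearance_rows if which == "a" else c.shape_rows
        Cz_block = self.latents.Cz[np.ix_(rows, rows)]
        return 0.5 * c.lambda1 * n_scale * np.trace(G) + 0.5 * c.lambda2 * float(
            np.sum(Cz_block * G)
        )

    # -- stage: shape basis ----------------------------------------------
    def shape_derivs(self, n):
        """Template-space shape gradient field and d×d Hessian field for
        image n: g_v = −(pushed residual)·∇a, H_v = ∇a h ∇aᵀ."""
        p = self.params
        a, defm = self.image_state(n, defm=self.defs[n])
        dv = lk.energy_derivs(self.dataset[n], a, defm, p.sigma2)
        ga = _spatial_gradient(_with_channel(a, p.noise), self.d)  # (*dims, C, d)
        gpush = _with_channel(dv.grad, p.noise)
        gs = -np.einsum("...c,...ca->...a", gpush, ga)
        if p.noise == lk.CATEGORICAL:
            Hs = np.einsum("...ij,...ia,...jb->...ab", dv.hess, ga, ga)
        else:
            Hs = dv.hess[..., None, None] * np.einsum(
                "...ca,...cb->...ab", ga, ga
            )
        return gs, Hs, dv

    def update_shape_basis(self):
        p, c = self.params, self.config
        n_scale = self.N if c.scale_penalty_by_N else 1.0
        rows = c.shape_rows
        for j, k in enumerate(rows):
            zrow = self.latents.Z[k]
            grad = np.zeros_like(p.Wv[j])
            hess = np.zeros(self.grid.dims + (self.d, self.d))
            used = False
            for n in range(self.N):
                if zrow[n] == 0.0:
                    continue
                gs, Hs, _ = self.shape_derivs(n)
                grad += zrow[n] * gs
                hess += zrow[n] ** 2 * Hs
                used = True
            if not used:
                continue
            WCz = np.einsum("l,l...->...", self.latents.Cz[rows][:, k], p.Wv)
            grad = grad + self.ops.Lv.apply(
                c.lambda1 * n_scale * p.Wv[j] + c.lambda2 * WCz
            )
            reg = c.lambda1 * n_scale + c.lambda2 * self.latents.Cz[k, k]
            step, _ = solve_regularized(
                hess / max(reg, 1e-12),
                self.ops.Lv,
                grad / max(reg, 1e-12),
                tol=c.solve_tol,
                raise_on_fail=False,
            )
            self._accept_shape_column(j, step)
        return True

    def _accept_shape_column(self, j, step):
        p, c = self.params, self.config
        zrow = self.latents.Z[c.shape_rows[j]]
        Gv = self.gram("v")
        base = -self.energies.sum() - self._basis_penalty("v", Gv)
        alpha = 1.0
        for _ in range(c.max_halvings):
            Wv_t = p.Wv.copy()
            Wv_t[j] = p.Wv[j] - alpha * step
            en_t = self.energies.copy()
            defs_t = {}
            for n in range(self.N):
                if zrow[n] == 0.0:
                    continue
                a_t, defm_t = self.image_state(n, Wv=Wv_t)
                defs_t[n] = defm_t
                en_t[n] = self.image_energy(n, a_t, defm_t)
            Gv_t = self.gram("v", Wv=Wv_t)
            obj_t = -en_t.sum() - self._basis_penalty("v", Gv_t)
            if obj_t > base:
                p.Wv = Wv_t
                self.energies = en_t
                for n, dfm in defs_t.items():
                    self.defs[n] = dfm
                return True
            alpha *= 0.5
        self.warnings.append("shape update: line search exhausted for a column")
        return False

    # -- stage: noise variance -------------------------------------------
    def update_sigma2(self):
        p = self.params
        if p.noise != lk.GAUSSIAN:
            return False
        ss, m = 0.0, 0
        for n in range(self.N):
            f = self.dataset[n]
            a, defm = self.image_state(n, defm=self.defs[n])
            ap = pull(a, defm)
            r = np.where(f.mask, ap - f.data, 0.0)
            r = np.where(np.isfinite(r), r, 0.0)
            ss += float(np.sum(r * r))
            m += f.n_observed
        p.sigma2 = lk.update_sigma2(ss, m, floor=self.sigma2_floor)
        for n in range(self.N):
            a, defm = self.image_state(n, defm=self.defs[n])
            self.energies[n] = self.image_energy(n, a, defm)
        return True

    # -- stage: latents ---------------------------------------------------
    def update_latents(self):
        c = self.config
        P0 = self.latent_prior_precision()
        S = np.zeros((c.K, c.K))
        for n in range(self.N):
            z, Hmode, energy, defm = latent_gn(
                self.dataset[n],
                self.params,
                self.ops,
                c,
                self.latents.Z[:, n].copy(),
                P0,
                n_iter=c.n_latent_iter,
            )
            self.latents.Z[:, n] = z
            self.defs[n] = defm
            self.energies[n] = energy
            S += _stable_inv(Hmode)
        self.latents.S = 0.5 * (S + S.T)
        self.latents.Cz = self.latents.Z @ self.latents.Z.T
        return True

    # -- stage: orthogonalisation ----------------------------------------
    def orthogonalise(self):
        result = orthogonalise(
            self.params, self.latents, self.wishart, self.config, self.ops
        )
        if result is None:
            return False
        self.params, self.latents, self.wishart, transform = result
        return True

    # -- the outer loop ---------------------------------------------------
    def run(self):
        c = self.config
        self.log(0, "init")
        for it in range(1, c.n_iter + 1):
            self.update_mean()
            self.log(it, "mean")
            self.update_appearance_basis()
            self.log(it, "appearance")
            self.update_shape_basis()
            self.log(it, "shape")
            if self.update_sigma2():
                self.log(it, "sigma2")
            if self.orthogonalise():
                self.log(it, "orthogonalise")
            self.update_latents()
            self.log(it, "latents")
            self.wishart, self.params.A_hat = update_precision(
                self.latents, self.wishart
            )
            self.log(it, "precision")
        return self.params, self.latents, self.wishart, self.history


def _stable_inv(H, ridge_frac=1e-8):
    K = H.shape[0]
    ridge = ridge_frac * max(np.trace(H), 1e-30) / K
    try:
        return np.linalg.inv(H + ridge * np.eye(K))
    except np.linalg.LinAlgError:
        return np.linalg.inv(H + (1e-6 * np.trace(H) / K + 1e-12) * np.eye(K))


def latent_gn(f, params, ops, config, z0, P0, n_iter=3, shoot_fn=None):
    """Gauss-Newton update of one image's latent code.

    Returns (mode z, Hessian at mode, final energy, final deformation).
    The likelihood Jacobian w.r.t. z_k in template space combines the
    appearance column Wᵃ_k with the shape column's first-order template
    perturbation −∇a·Wᵛ_k.
    """
    c = config
    p = params
    z = z0.astype(float).copy()
    d = p.grid.ndim

    def state(zc):
        a, v = reconstruct(p, zc)
        defm = geodesic_shoot(v, ops.Lv, c.n_shoot_steps) if shoot_fn is None else shoot_fn(v)
        return a, defm

    def total_energy(zc, a=None, defm=None):
        if a is None:
            a, defm = state(zc)
        e = lk.energy_only(f, a, defm, p.sigma2)
        return e + 0.5 * float(z_prior(zc)), a, defm

    def z_prior(zc):
        return zc @ P0 @ zc

    a, defm = state(z)
    energy = lk.energy_only(f, a, defm, p.sigma2)
    obj = energy + 0.5 * float(z_prior(z))
    Hmode = P0.copy()

    for _ in range(n_iter):
        dv = lk.energy_derivs(f, a, defm, p.sigma2)
        ga = _spatial_gradient(_with_channel(a, p.noise), d)
        gpush = _with_channel(dv.grad, p.noise)
        # template-space Jacobian fields J_k, one per latent dimension
        J = np.zeros((c.K,) + gpush.shape)
        for j, k in enumerate(c.appearance_rows):
            J[k] += _with_channel(p.Wa[j], p.noise)
        for j, k in enumerate(c.shape_rows):
            J[k] += -np.einsum("...ca,...a->...c", ga, p.Wv[j])
        C = gpush.shape[-1]
        Jf = J.reshape(c.K, -1, C)
        grad = np.einsum("kmi,mi->k", Jf, gpush.reshape(-1, C)) + P0 @ z
        if p.noise == lk.CATEGORICAL:
            Hlik = np.einsum("kmi,mij,lmj->kl", Jf, dv.hess.reshape(-1, C, C), Jf)
        else:
            h = dv.hess.reshape(-1, 1)
            Hlik = np.einsum("kmi,mi,lmi->kl", Jf, h, Jf)
        H = Hlik + P0
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H + 0.0 * np.eye(c.K), grad)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.trace(H) / c.K
            step = np.linalg.solve(H + ridge * np.eye(c.K), grad)
        accepted = False
        alpha = 1.0
        for _ in range(c.max_halvings):
            z_t = z - alpha * step
            obj_t, a_t, defm_t = total_energy(z_t)
            if obj_t < obj:
                z, obj, a, defm = z_t, obj_t, a_t, defm_t
                energy = obj - 0.5 * float(z_prior(z))
                accepted = True
                break
            alpha *= 0.5
        Hmode = H
        if not accepted:
            break
    return z, Hmode, energy, defm


# ---------------------------------------------------------------------------
# orthogonalisation
# ---------------------------------------------------------------------------


def _eig_floor(M, floor_frac=1e-12):
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    floor = floor_frac * max(vals.max(), 1e-30)
    return np.maximum(vals, floor), vecs


def _block_transform(Cz, C):
    """Initial T for one latent block from the two eigendecompositions and
    the connecting SVD; diagonalises both T Cz Tᵀ and T⁻ᵀ C T⁻¹."""
    dz, Vz = _eig_floor(Cz)
    dw, Vw = _eig_floor(C)
    Mid = np.sqrt(dw)[:, None] * (Vw.T @ Vz) * np.sqrt(dz)[None, :]
    U, Dg, Vt = np.linalg.svd(Mid)
    T = Dg[:, None] * Vt @ np.diag(1.0 / np.sqrt(dz)) @ Vz.T
    return T


def _scaling_fixed_point(T, Cz_S, C, wishart, config, N):
    """Iterate the diagonal-scaling / precision fixed point.

    Minimises the q-dependent part of the joint objective:
    λ1·n_scale·Σ e^{-2q} dc  (basis penalty)  +  λ1·Tr(Q B Q Â) (latent term),
    alternated with the Wishart refresh Â = (N+ν0)(Q B Q + Λ0⁻¹)⁻¹,
    where B = T (Cᶻ+S) Tᵀ and dc = diag(T⁻ᵀ C T⁻¹).
    """
    c = config
    K = T.shape[0]
    n_scale = N if c.scale_penalty_by_N else 1.0
    Tinv = np.linalg.inv(T)
    dc = np.einsum("ij,jk,ik->i", Tinv.T, C, Tinv.T)
    # only rescale directions with genuine basis energy; scaling an unused
    # latent has no counter-weight and would run away
    active = dc > 1e-12 * max(dc.max(), 1e-30)
    dc = np.maximum(dc, 1e-30)
    B = T @ Cz_S @ T.T
    B = 0.5 * (B + B.T)
    q = np.zeros(K)
    if not active.any():
        return q

    def phi(qv, A):
        e = np.exp(qv)
        return float(
            c.lambda1 * n_scale * np.sum(np.exp(-2 * qv) * dc)
            + c.lambda1 * np.einsum("i,ij,j,ij->", e, B, e, A)
        )

    for _ in range(100):
        e = np.exp(q)
        QBQ = e[:, None] * B * e[None, :]
        A = (N + wishart.nu0) * np.linalg.inv(QBQ + wishart.Lambda0_inv)
        A = 0.5 * (A + A.T)
        # Gauss-Newton step on q
        t2 = c.lambda1 * (B * A) * e[:, None] * e[None, :]
        g = -2.0 * c.lambda1 * n_scale * np.exp(-2 * q) * dc + 2.0 * t2.sum(axis=1)
        H = 2.0 * t2.copy()
        np.fill_diagonal(
            H, 4.0 * c.lambda1 * n_scale * np.exp(-2 * q) * dc + 2.0 * t2.sum(axis=1) + 2.0 * np.diag(t2)
        )
        g = np.where(active, g, 0.0)
        try:
            dq = np.linalg.solve(H + 1e-12 * np.eye(K), g)
        except np.linalg.LinAlgError:
            break
        dq = np.where(active, dq, 0.0)
        base = phi(q, A)
        alpha, ok = 1.0, False
        for _ in range(20):
            q_t = q - alpha * dq
            if phi(q_t, A) < base:
                q, ok = q_t, True
                break
            alpha *= 0.5
        if not ok or np.linalg.norm(alpha * dq) < 1e-8:
            break
    return q


def orthogonalise(params, latents, wishart, config, ops):
    """Reparameterise so latent rows are orthogonal and the basis Gram is
    diagonal, with an optimal diagonal rescaling; reconstructions W·z are
    exactly preserved.  Returns (params, latents, wishart, OrthoTransform)
    or None when the bases are still all zero (nothing to orthogonalise)."""
    c = config
    Ga = ops.La.gram(list(params.Wa))
    Gv = ops.Lv.gram(list(params.Wv))
    if np.trace(Ga) + np.trace(Gv) < 1e-20:
        return None
    K, N = latents.Z.shape
    Cz = latents.Cz
    Cz_S = Cz + latents.S

    if c.mode == SHARED:
        blocks = [(np.arange(K), Ga + Gv)]
    else:
        blocks = [
            (np.arange(c.Ka), Ga),
            (np.arange(c.Ka, K), Gv),
        ]
    T = np.eye(K)
    Cfull = np.zeros((K, K))
    for rows, Cblk in blocks:
        if len(rows) == 0 or np.trace(Cblk) < 1e-20:
            continue  # empty or still-zero basis block: leave untouched
        T[np.ix_(rows, rows)] = _block_transform(Cz[np.ix_(rows, rows)], Cblk)
        Cfull[np.ix_(rows, rows)] = Cblk
    q = _scaling_fixed_point(T, Cz_S, Cfull, wishart, config, N)
    Qd = np.exp(q)
    Tfull = Qd[:, None] * T
    Tinv = np.linalg.inv(Tfull)

    new = params.copy()
    Z = Tfull @ latents.Z
    S = Tfull @ latents.S @ Tfull.T
    if c.mode == SHARED:
        new.Wa = np.einsum("k...,kj->j...", params.Wa, Tinv)
        new.Wv = np.einsum("k...,kj->j...", params.Wv, Tinv)
    else:
        new.Wa = np.einsum("k...,kj->j...", params.Wa, Tinv[: c.Ka, : c.Ka])
        new.Wv = np.einsum("k...,kj->j...", params.Wv, Tinv[c.Ka :, c.Ka :])
    latents_new = LatentPosterior(Z, 0.5 * (S + S.T), Z @ Z.T)
    wishart_new, A_hat = update_precision(latents_new, wishart)
    new.A_hat = A_hat
    return new, latents_new, wishart_new, OrthoTransform(Tfull, Qd)


# ---------------------------------------------------------------------------
# free-function joint log-probability (independent of the engine caches)
# ---------------------------------------------------------------------------


def joint_log_prob(params, dataset, latents, wishart, config, ops=None):
    """Evaluate the joint log-probability from scratch (constants dropped)."""
    ops = ops or Operators.from_config(params.grid, config)
    c = config
    N = len(dataset)
    total = 0.0
    for n, f in enumerate(dataset):
        a, v = reconstruct(params, latents.Z[:, n])
        defm = geodesic_shoot(v, ops.Lv, c.n_shoot_steps)
        total -= lk.energy_only(f, a, defm, params.sigma2)
    total -= 0.5 * ops.Lmu.quad_form(params.mu)
    Ga = ops.La.gram(list(params.Wa))
    Gv = ops.Lv.gram(list(params.Wv))
    n_scale = N if c.scale_penalty_by_N else 1.0
    total -= 0.5 * c.lambda1 * n_scale * (np.trace(Ga) + np.trace(Gv))
    if c.mode == SHARED:
        Gfull = Ga + Gv
    else:
        Gfull = np.zeros((c.K, c.K))
        Gfull[: c.Ka, : c.Ka] = Ga
        Gfull[c.Ka :, c.Ka :] = Gv
    total -= 0.5 * c.lambda2 * float(np.sum(latents.Cz * Gfull))
    sign, logdet = np.linalg.slogdet(params.A_hat)
    tr = float(np.sum((latents.Cz + wishart.Lambda0_inv) * params.A_hat))
    total += 0.5 * c.lambda1 * ((N + wishart.nu0 - c.K - 1) * logdet - tr)
    return float(total)


# ---------------------------------------------------------------------------
# public Model / Results objects
# ---------------------------------------------------------------------------


class ShapeAppearanceModel:
    """Shape-and-appearance factor model over a collection of images.

    Parameters
    ----------
    images : sequence of ndarray or ObservedImage
        All on the same lattice.  NaN marks missing voxels.
    config : FitConfig
    voxel_size : tuple, optional
        Spacing in mm (default isotropic 1 mm).
    """

    def __init__(self, images, config: FitConfig = None, voxel_size=None):
        self.config = config or FitConfig()
        self.dataset = [
            im
            if isinstance(im, lk.ObservedImage)
            else lk.ObservedImage(np.asarray(im, dtype=float), self.config.noise)
            for im in images
        ]
        if not self.dataset:
            raise ValueError("empty dataset")
        shape = self.dataset[0].data.shape
        for f in self.dataset:
            if f.data.shape != shape:
                raise ValueError("all images must share one lattice")
            if f.model != self.config.noise:
                raise ValueError("image noise tag disagrees with config")
        dims = shape[:-1] if self.config.noise == lk.CATEGORICAL else shape
        self.grid = GridSpec(dims, voxel_size)
        self.ops = Operators.from_config(self.grid, self.config)

    def fit(self):
        """Run the alternating Gauss-Newton fitting loop."""
        from .results import ShapeAppearanceResults

        engine = _Fitter(self.dataset, self.config, self.grid, self.ops)
        params, latents, wishart, history = engine.run()
        return ShapeAppearanceResults(
            self, params, latents, wishart, history, engine.warnings
        )
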