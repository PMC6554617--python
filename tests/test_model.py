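"""Model construction, single-stage updates, orthogonalisation, fitting."""

import numpy as np
import pytest

from shapeappear import (
    FitConfig,
    GridSpec,
    LatentPosterior,
    ObservedImage,
    ShapeAppearanceModel,
    WishartState,
    init_latents,
    joint_log_prob,
    orthogonalise,
    reconstruct,
    update_precision,
)
from shapeappear import likelihoods as lk
from shapeappear.diffeo import geodesic_shoot, pull
from shapeappear.model import ModelParams, Operators, _Fitter, init_model, latent_gn

from conftest import smooth_field
from test_operators import dense_scalar_operator


# -- initialisation ---------------------------------------------------------


def test_init_latents_rows_exactly_orthogonal(rng):
    for N, K in [(12, 3), (5, 5), (40, 1)]:
        Z = init_latents(N, K, rng)
        assert np.abs(Z @ Z.T - N * np.eye(K)).max() < 1e-10


def test_init_latents_deterministic_and_validated():
    Z1 = init_latents(10, 3, np.random.default_rng(7))
    Z2 = init_latents(10, 3, np.random.default_rng(7))
    assert np.array_equal(Z1, Z2)
    with pytest.raises(ValueError):
        init_latents(2, 3, np.random.default_rng(0))


def test_init_model_mean_and_precision(rng):
    grid = GridSpec((6, 6))
    data = [rng.standard_normal((6, 6)) for _ in range(10)]
    data[0][2, 2] = np.nan
    ds = [ObservedImage(d, "gaussian") for d in data]
    cfg = FitConfig(K=2, n_iter=1)
    params, latents, wishart = init_model(ds, cfg, grid)
    stack = np.stack(data)
    expected_mu = np.nanmean(stack, axis=0)
    finite = np.isfinite(expected_mu)
    assert np.allclose(params.mu[finite], expected_mu[finite])
    assert np.abs(params.Wa).max() == 0 and np.abs(params.Wv).max() == 0
    assert np.abs(latents.Cz - 10 * np.eye(2)).max() < 1e-9
    # with nu0=K and Lambda0=I/nu0: Â = (N+ν0)(N·I+ν0·I)⁻¹ = I
    assert np.allclose(params.A_hat, np.eye(2), atol=1e-12)


# -- reconstruct ------------------------------------------------------------


def test_reconstruct_zero_latent_gives_template(rng):
    grid = GridSpec((6, 6))
    params = ModelParams(
        grid, "shared", "gaussian",
        rng.standard_normal((6, 6)),
        rng.standard_normal((3, 6, 6)),
        rng.standard_normal((3, 6, 6, 2)),
        1.0, np.eye(3),
    )
    a, v = reconstruct(params, np.zeros(3))
    assert np.array_equal(a, params.mu)
    assert np.abs(v).max() == 0


def test_reconstruct_matches_explicit_sum_and_linearity(rng):
    grid = GridSpec((6, 6))
    params = ModelParams(
        grid, "shared", "gaussian",
        rng.standard_normal((6, 6)),
        rng.standard_normal((3, 6, 6)),
        rng.standard_normal((3, 6, 6, 2)),
        1.0, np.eye(3),
    )
    z = rng.standard_normal(3)
    a, v = reconstruct(params, z)
    a_expl = params.mu + sum(z[k] * params.Wa[k] for k in range(3))
    v_expl = sum(z[k] * params.Wv[k] for k in range(3))
    assert np.abs(a - a_expl).max() < 1e-12
    assert np.abs(v - v_expl).max() < 1e-12
    a2, v2 = reconstruct(params, 2 * z)
    assert np.abs((a2 - params.mu) - 2 * (a - params.mu)).max() < 1e-12
    assert np.abs(v2 - 2 * v).max() < 1e-12


def test_reconstruct_split_mode(rng):
    grid = GridSpec((6, 6))
    params = ModelParams(
        grid, "split", "gaussian",
        rng.standard_normal((6, 6)),
        rng.standard_normal((2, 6, 6)),
        rng.standard_normal((3, 6, 6, 2)),
        1.0, np.eye(5),
    )
    z = rng.standard_normal(5)
    a, v = reconstruct(params, z)
    assert np.allclose(a, params.mu + np.einsum("k,k...->...", z[:2], params.Wa))
    assert np.allclose(v, np.einsum("k,k...->...", z[2:], params.Wv))


# -- Wishart precision update ----------------------------------------------


def test_precision_prior_only_gives_identity():
    K = 3
    Z = np.zeros((K, 0))
    latents = LatentPosterior(Z, np.zeros((K, K)), np.zeros((K, K)))
    wishart = WishartState(K * np.eye(K), float(K))  # Λ0 = I/ν0
    new, A = update_precision(latents, wishart)
    assert np.allclose(A, np.eye(K), atol=1e-12)
    assert new.nu == K


def test_precision_scalar_worked_case():
    # K=1, ν0=1, Λ0=1 (Λ0⁻¹=1), Cz+S=3, N=4: Â = 5·(3+1)⁻¹ = 1.25
    Z = np.full((1, 4), np.sqrt(3.0 / 4.0))
    latents = LatentPosterior(Z, np.zeros((1, 1)), Z @ Z.T)
    wishart = WishartState(np.eye(1), 1.0)
    _, A = update_precision(latents, wishart)
    assert np.isclose(A[0, 0], 1.25)


def test_precision_homogeneity():
    rngl = np.random.default_rng(3)
    Z = rngl.standard_normal((2, 6))
    S = np.eye(2) * 0.3
    latents = LatentPosterior(Z, S, Z @ Z.T)
    wishart = WishartState(2 * np.eye(2), 2.0)
    _, A1 = update_precision(latents, wishart)
    latents2 = LatentPosterior(np.sqrt(2) * Z, 2 * S, 2 * Z @ Z.T)
    wishart2 = WishartState(4 * np.eye(2), 2.0)
    _, A2 = update_precision(latents2, wishart2)
    assert np.allclose(A2, 0.5 * A1)


# -- mean update ------------------------------------------------------------


def make_engine(rng, N=4, K=2, dims=(8, 8), noise="gaussian", **cfg_kw):
    grid = GridSpec(dims)
    shape = dims + (3,) if noise == "categorical" else dims
    if noise == "gaussian":
        data = [rng.standard_normal(shape) for _ in range(N)]
    elif noise == "bernoulli":
        data = [rng.random(shape) for _ in range(N)]
    else:
        raw = [rng.random(shape) for _ in range(N)]
        data = [r / r.sum(axis=-1, keepdims=True) for r in raw]
    cfg = FitConfig(K=K, noise=noise, n_iter=1, **cfg_kw)
    ds = [ObservedImage(d, noise) for d in data]
    return _Fitter(ds, cfg, grid), ds


def test_update_mean_stationary_at_optimum(rng):
    # identical images, zero bases, mu already the image: no change
    grid = GridSpec((8, 8))
    img = rng.standard_normal((8, 8))
    ds = [ObservedImage(img.copy(), "gaussian") for _ in range(4)]
    cfg = FitConfig(K=2, n_iter=1, omega_mu=(1e-8, 0, 0))
    eng = _Fitter(ds, cfg, grid)
    mu_before = eng.params.mu.copy()  # init mean = the image itself
    assert np.allclose(mu_before, img)
    eng.update_mean()
    assert np.abs(eng.params.mu - img).max() < 1e-6


def test_update_mean_matches_closed_form_solve(rng):
    # from mu0=0 with identity deformations, one GN step lands on
    # (N/σ²·I + Lμ)⁻¹ (N/σ²) f̄ — checked against a dense solve
    grid = GridSpec((8, 8))
    imgs = [rng.standard_normal((8, 8)) for _ in range(3)]
    ds = [ObservedImage(im, "gaussian") for im in imgs]
    cfg = FitConfig(K=1, n_iter=1, omega_mu=(0.05, 0.4, 0.0))
    eng = _Fitter(ds, cfg, grid)
    eng.params.mu = np.zeros((8, 8))
    eng.params.sigma2 = 0.7
    eng.refresh_all()
    eng.update_mean()
    fbar = np.mean(imgs, axis=0)
    Ld = dense_scalar_operator(grid, (0.05, 0.4, 0.0))
    A = (3 / 0.7) * np.eye(64) + Ld
    expected = np.linalg.solve(A, (3 / 0.7) * fbar.ravel()).reshape(8, 8)
    assert np.abs(eng.params.mu - expected).max() < 1e-6


def test_stage_updates_never_decrease_objective(rng):
    eng, _ = make_engine(rng, N=5, K=2)
    obj = eng.objective()
    for stage in (
        eng.update_mean,
        eng.update_appearance_basis,
        eng.update_shape_basis,
        eng.update_sigma2,
        eng.update_latents,
    ):
        stage()
        new = eng.objective()
        assert new >= obj - 1e-6 * max(1, abs(obj))
        obj = new


# -- latent update ----------------------------------------------------------


def test_latent_mode_stays_zero_for_template_image(rng):
    grid = GridSpec((8, 8))
    mu = rng.standard_normal((8, 8))
    params = ModelParams(
        grid, "shared", "gaussian", mu,
        0.3 * np.stack([smooth_field(grid, rng, n_comp=1)] * 1),
        0.5 * np.stack([smooth_field(grid, rng)] * 1),
        0.2, np.eye(1),
    )
    cfg = FitConfig(K=1, n_iter=1)
    ops = Operators.from_config(grid, cfg)
    f = ObservedImage(mu.copy(), "gaussian")
    P0 = cfg.lambda1 * params.A_hat + cfg.lambda2 * (
        ops.La.gram(list(params.Wa)) + ops.Lv.gram(list(params.Wv))
    )
    z, H, energy, _ = latent_gn(f, params, ops, cfg, np.zeros(1), P0, n_iter=3)
    assert np.abs(z).max() < 1e-8


def test_latent_shrinkage_matches_1d_closed_form(rng):
    # linear no-warp case: ẑ = wᵀ(f−μ)/σ² / (wᵀw/σ² + P0)
    grid = GridSpec((8, 8))
    mu = rng.standard_normal((8, 8))
    w = smooth_field(grid, rng, n_comp=1)
    params = ModelParams(
        grid, "shared", "gaussian", mu, np.stack([w]),
        np.zeros((1, 8, 8, 2)), 0.3, np.eye(1) * 2.0,
    )
    cfg = FitConfig(K=1, n_iter=1, lambda1=0.9, lambda2=0.1)
    ops = Operators.from_config(grid, cfg)
    z_star = 1.4
    f = ObservedImage(mu + z_star * w, "gaussian")
    P0 = cfg.lambda1 * params.A_hat + cfg.lambda2 * ops.La.gram([w])
    z, _, _, _ = latent_gn(f, params, ops, cfg, np.zeros(1), P0, n_iter=2)
    num = float(np.sum(w * (f.data - mu))) / 0.3
    den = float(np.sum(w * w)) / 0.3 + P0[0, 0]
    z_expected = num / den
    assert abs(z[0] - z_expected) < 1e-8
    assert 0 < z[0] < z_star  # shrunk toward the prior mean
    # stronger prior precision shrinks further
    P0b = P0 * 10
    zb, _, _, _ = latent_gn(f, params, ops, cfg, np.zeros(1), P0b, n_iter=2)
    assert abs(zb[0]) < abs(z[0])


# -- orthogonalisation ------------------------------------------------------


def make_state(rng, K=3, N=12, mode="shared", Ka=None, Kv=None):
    grid = GridSpec((8, 8))
    kw = dict(K=K) if mode == "shared" else dict(mode=mode, Ka=Ka, Kv=Kv)
    cfg = FitConfig(n_iter=1, **kw)
    ops = Operators.from_config(grid, cfg)
    params = ModelParams(
        grid, mode, "gaussian",
        rng.standard_normal((8, 8)),
        np.stack([0.5 * smooth_field(grid, rng, n_comp=1) for _ in range(cfg.Ka)]),
        np.stack([smooth_field(grid, rng) for _ in range(cfg.Kv)]),
        0.2, np.eye(cfg.K),
    )
    Z = rng.standard_normal((cfg.K, N))
    S = 0.1 * np.eye(cfg.K)
    latents = LatentPosterior(Z, S, Z @ Z.T)
    wishart = WishartState(cfg.K * np.eye(cfg.K), float(cfg.K))
    return params, latents, wishart, cfg, ops


def test_orthogonalise_preserves_reconstructions(rng):
    params, latents, wishart, cfg, ops = make_state(rng)
    p2, l2, w2, tr = orthogonalise(params, latents, wishart, cfg, ops)
    for n in range(5):
        a1, v1 = reconstruct(params, latents.Z[:, n])
        a2, v2 = reconstruct(p2, l2.Z[:, n])
        assert np.abs(a1 - a2).max() < 1e-8
        assert np.abs(v1 - v2).max() < 1e-8


def test_orthogonalise_diagonalises(rng):
    params, latents, wishart, cfg, ops = make_state(rng)
    p2, l2, w2, tr = orthogonalise(params, latents, wishart, cfg, ops)
    Cz = l2.Z @ l2.Z.T
    off = Cz - np.diag(np.diag(Cz))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(Cz)).max()
    G = ops.La.gram(list(p2.Wa)) + ops.Lv.gram(list(p2.Wv))
    offG = G - np.diag(np.diag(G))
    assert np.abs(offG).max() < 1e-6 * np.abs(np.diag(G)).max()


def test_orthogonalise_split_mode_block_structure(rng):
    params, latents, wishart, cfg, ops = make_state(rng, K=None, mode="split", Ka=2, Kv=2)
    p2, l2, w2, tr = orthogonalise(params, latents, wishart, cfg, ops)
    # transform must not mix appearance and shape latents
    assert np.abs(tr.T[:2, 2:]).max() == 0.0
    assert np.abs(tr.T[2:, :2]).max() == 0.0
    for n in range(4):
        a1, v1 = reconstruct(params, latents.Z[:, n])
        a2, v2 = reconstruct(p2, l2.Z[:, n])
        assert np.abs(a1 - a2).max() < 1e-8
        assert np.abs(v1 - v2).max() < 1e-8


def test_orthogonalise_idempotent_up_to_signed_permutation(rng):
    params, latents, wishart, cfg, ops = make_state(rng)
    p2, l2, w2, _ = orthogonalise(params, latents, wishart, cfg, ops)
    _, _, _, tr2 = orthogonalise(p2, l2, w2, cfg, ops)
    T = tr2.T
    # one entry of magnitude ~1 per row/column, everything else ~0
    P = np.abs(T)
    assert ((P > 0.5).sum(axis=0) == 1).all()
    assert ((P > 0.5).sum(axis=1) == 1).all()
    assert np.abs(P[P > 0.5] - 1.0).max() < 1e-6
    assert np.abs(P[P <= 0.5]).max() < 1e-6


# -- joint log-probability --------------------------------------------------


def naive_joint_log_prob(params, dataset, latents, wishart, cfg, ops):
    """Term-by-term literal reimplementation for the toy oracle."""
    N = len(dataset)
    K = cfg.K
    lam1, lam2 = cfg.lambda1, cfg.lambda2
    total = 0.0
    for n, f in enumerate(dataset):
        z = latents.Z[:, n]
        a = params.mu + np.einsum("k,k...->...", z, params.Wa)
        v = np.einsum("k,k...->...", z, params.Wv)
        psi = geodesic_shoot(v, ops.Lv, cfg.n_shoot_steps)
        ap = pull(a, psi)
        r = ap - f.data
        total -= 0.5 / params.sigma2 * np.sum(r * r) + 0.5 * r.size * (
            np.log(params.sigma2) + np.log(2 * np.pi)
        )
    total -= 0.5 * np.sum(params.mu * ops.Lmu.apply(params.mu))
    Ga = np.array([[np.sum(wi * ops.La.apply(wj)) for wj in params.Wa] for wi in params.Wa])
    Gv = np.array([[np.sum(wi * ops.Lv.apply(wj)) for wj in params.Wv] for wi in params.Wv])
    total -= 0.5 * lam1 * N * (np.trace(Ga) + np.trace(Gv))
    Cz = latents.Z @ latents.Z.T
    total -= 0.5 * lam2 * np.trace(Cz @ (Ga + Gv))
    A = params.A_hat
    total += 0.5 * lam1 * (
        (N + wishart.nu0 - K - 1) * np.linalg.slogdet(A)[1]
        - np.trace((Cz + wishart.Lambda0_inv) @ A)
    )
    return float(total)


def test_joint_log_prob_matches_naive_reimplementation(rng):
    params, latents, wishart, cfg, ops = make_state(rng, K=2, N=4)
    data = [ObservedImage(rng.standard_normal((8, 8)), "gaussian") for _ in range(4)]
    got = joint_log_prob(params, data, latents, wishart, cfg, ops)
    want = naive_joint_log_prob(params, data, latents, wishart, cfg, ops)
    assert abs(got - want) < 1e-8 * max(1, abs(want))


def test_joint_log_prob_monotone_in_penalty_weights(rng):
    params, latents, wishart, cfg, ops = make_state(rng, K=2, N=4)
    data = [ObservedImage(rng.standard_normal((8, 8)), "gaussian") for _ in range(4)]
    base = joint_log_prob(params, data, latents, wishart, cfg, ops)
    cfg2 = FitConfig(K=2, n_iter=1, lambda2=cfg.lambda2 * 3)
    worse = joint_log_prob(params, data, latents, wishart, cfg2, ops)
    assert worse <= base + 1e-9


# -- fit --------------------------------------------------------------------


def test_fit_seeded_runs_are_identical(rng):
    grid_data = [np.random.default_rng(5).standard_normal((8, 8)) for _ in range(6)]
    cfg = dict(K=2, n_iter=2, seed=11)
    r1 = ShapeAppearanceModel(grid_data, FitConfig(**cfg)).fit()
    r2 = ShapeAppearanceModel(grid_data, FitConfig(**cfg)).fit()
    assert np.array_equal(r1.params.mu, r2.params.mu)
    assert np.array_equal(r1.latents.Z, r2.latents.Z)
    assert r1.history[-1]["objective"] == r2.history[-1]["objective"]


def test_fit_zero_k_shape_reduces_to_template_and_appearance(rng):
    # shape-free ablation still runs and is monotone
    data = [rng.standard_normal((8, 8)) for _ in range(6)]
    cfg = FitConfig(mode="split", Ka=2, Kv=0, n_iter=2, seed=0)
    res = ShapeAppearanceModel(data, cfg).fit()
    assert res.monotonicity_violations() == []
    assert res.params.Wv.shape[0] == 0


def test_single_shape_mode_recovery_displacement_correlation():
    """Data generated by warping a template with one known velocity mode:
    the recovered mode's shooting displacement must correlate > 0.9 with
    the true displacement field."""
    from shapeappear import ShapeAppearanceModel, geodesic_shoot
    from shapeappear.synth import make_ground_truth_model, render_dataset

    grid = GridSpec((16, 16))
    rng = np.random.default_rng(3)
    gen = FitConfig(K=1, seed=3)
    gt = make_ground_truth_model(grid, K=1, rng=rng, config=gen, appearance_amp=0.0)
    gt = render_dataset(gt, 12, rng, noise_level=0.02)
    res = ShapeAppearanceModel([f.data for f in gt.images], FitConfig(K=1, n_iter=8, seed=1)).fit()
    cvel = np.corrcoef(gt.params.Wv[0].ravel(), res.params.Wv[0].ravel())[0, 1]
    w = res.params.Wv[0] * np.sign(cvel)
    w = w * np.abs(gt.params.Wv[0]).max() / np.abs(w).max()
    d_true = geodesic_shoot(gt.params.Wv[0], gt.ops.Lv, 8).displacement
    d_rec = geodesic_shoot(w, res.model.ops.Lv, 8).displacement
    assert np.corrcoef(d_true.ravel(), d_rec.ravel())[0, 1] > 0.9
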