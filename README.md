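# shapeappear

Unsupervised learning of **shape and appearance models** from collections of
2D or 3D images, without annotations. The package is aimed at biological and
medical image analysis — groupwise template building, low-dimensional
encoding of anatomy, generative classification, and imputation of missing
image regions (e.g. hospital scans with restricted fields of view).

## The model

Every image `f_n` is explained by K latent variables `z_n` driving two
linear bases at once:

```
appearance:   a_n = μ + Wᵃ z_n                    (template perturbation)
shape:        v_n = Wᵛ z_n   →  ψ_n = Exp(v_n)    (geodesic shooting, LDDMM)
observation:  f_n ~ p(f | a_n ∘ ψ_n)              (Gaussian / Bernoulli / categorical)
```

The deformation `ψ_n` is a diffeomorphism obtained by integrating the
EPDiff equations from the initial velocity `v_n`, so shape variability is
always invertible and topology-preserving; whatever deformations cannot
express (topology change, intensity variation) is absorbed by the
appearance basis. Latents carry a `N(0, A⁻¹)` prior whose precision `A` is
inferred with a conjugate Wishart model; basis columns carry Sobolev
smoothness priors (membrane, bending, linear-elastic and divergence
penalties) applied spectrally under periodic boundary conditions.

Fitting alternates Gauss-Newton updates of the template and both bases
(each safeguarded by a backtracking line search on the joint
log-probability), an orthogonalisation of the latent rows, Gauss-Newton
latent updates with Laplace uncertainty, and the closed-form Wishart
update. Missing voxels (NaN) are simply ignored by every energy and
gradient. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import shapeappear as sa

rng = np.random.default_rng(0)
grid = sa.GridSpec((24, 24))

# a known ground-truth model: smooth bases, blob+texture template
truth = sa.make_ground_truth_model(grid, K=2, rng=rng, config=sa.FitConfig(K=2, seed=0))
truth = sa.render_dataset(truth, N=24, rng=rng, noise_level=0.05)

# fit a fresh model to the rendered images
model = sa.ShapeAppearanceModel(
    [f.data for f in truth.images],
    sa.FitConfig(K=2, noise="gaussian", n_iter=6, seed=1),
)
res = model.fit()
print(res.summary())
```

```
Shape and appearance model
==========================================
noise model      : gaussian
latent mode      : shared (K=2)
grid             : (24, 24) @ (1.0, 1.0) mm
images           : 24
outer iterations : 6
sigma            : 0.11539
final objective  : 10080.7
monotonicity     : 0 violations in safeguarded stages
latent sd (Â^-1) : 6.09, 2.67
latent modes rms : 4.88
warnings         : 3
```

`sigma` is the fitted observation noise (the data were rendered at 0.05;
six iterations of a 2-mode fit get partway there), the objective is the
joint log-probability logged after every stage, and the latent standard
deviations come from the expected precision `Â` — the model has organised
the population into one dominant and one secondary mode. The `warnings`
count is line searches that kept the previous value rather than accept a
non-improving step.

Encoding a held-out image and filling in a missing rectangle:

```python
test = sa.render_dataset(
    sa.GroundTruth(truth.params, truth.config, truth.ops, None, [], []),
    N=1, rng=np.random.default_rng(7), noise_level=0.05,
)
img = test.images[0].data.copy()
img[sa.random_rectangle_mask((24, 24), 0.25, np.random.default_rng(3))] = np.nan
pred, enc, score = res.impute(img, truth=test.images[0].data)
print(f"latent code: {np.round(enc.z_hat, 3)}")
print(f"log evidence: {enc.log_evidence:.1f}")
print(f"held-out log-likelihood per voxel: {score:.3f}")
```

```
latent code: [0.836 1.264]
log evidence: 302.0
held-out log-likelihood per voxel: 0.748
```

The image is encoded from its observed 75% alone; the hidden quarter is
predicted at 0.748 nats per voxel — a mean-intensity baseline scores −4.36
on the same hidden voxels under the same fitted noise model.

## Command line

```
shapeappear simulate --out-dir sim --n-images 32 --dims 32,32 --k 3 --seed 0
shapeappear train sim/img*.npy --k 3 --iters 8 --seed 1 --out model.npz --log fit.log
shapeappear encode model.npz sim/img0000.npy
shapeappear classify test.npy --model digits0.npz --model digits1.npz
shapeappear sample model.npz --out-dir samples --n-samples 8
shapeappear impute model.npz masked.npy --out filled.npy
shapeappear crossval sim/img*.npy --mask-fraction 0.25
```

Images travel as NIfTI (3D), PNG or raw `.npy`; NaN marks missing voxels.
A checkpoint is a single `.npz` of named arrays plus a JSON echo of the
configuration. Every run records its seed and resolved settings.

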