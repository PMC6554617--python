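"""Results object returned by :meth:`ShapeAppearanceModel.fit`."""

from __future__ import annotations

import numpy as np

from . import inference as inf
from . import likelihoods as lk
from .diffeo import geodesic_shoot, pull
from .model import reconstruct


class ShapeAppearanceResults:
    """Fitted estimates, latent posterior, diagnostics and downstream uses.

    Attributes
    ----------
    params : ModelParams
        μ, Wᵃ, Wᵛ, σ², Â point estimates.
    latents : LatentPosterior
        Modes Ẑ, aggregate Laplace covariance S and Cᶻ = ẐẐᵀ.
    wishart : WishartState
    history : list of dict
        Joint log-probability after every fitting stage.
    """

    #: stages whose update is safeguarded (line search or exact M-step);
    #: the objective must not decrease across these
    MONOTONE_STAGES = frozenset({"mean", "appearance", "shape", "sigma2", "latents"})

    def __init__(self, model, params, latents, wishart, history, warnings=None):
        self.model = model
        self.config = model.config
        self.params = params
        self.latents = latents
        self.wishart = wishart
        self.history = history
        self.warnings = warnings or []

    # -- diagnostics ------------------------------------------------------
    @property
    def objective_trace(self):
        return np.array([h["objective"] for h in self.history])

    def monotonicity_violations(self, tol: float = 1e-6):
        """Line-searched stages whose logged objective decreased by > tol."""
        out = []
        for prev, cur in zip(self.history, self.history[1:]):
            if cur["stage"] in self.MONOTONE_STAGES:
                drop = prev["objective"] - cur["objective"]
                if drop > tol * max(1.0, abs(prev["objective"])):
                    out.append((cur["iter"], cur["stage"], drop))
        return out

    def summary(self) -> str:
        c, p = self.config, self.params
        lines = [
            "Shape and appearance model",
            "=" * 42,
            f"noise model      : {p.noise}",
            f"latent mode      : {p.mode} (K={c.K}"
            + (f", Ka={c.Ka}, Kv={c.Kv})" if p.mode == "split" else ")"),
            f"grid             : {p.grid.dims} @ {p.grid.voxel_size} mm",
            f"images           : {self.latents.Z.shape[1]}",
            f"outer iterations : {c.n_iter}",
        ]
        if p.noise == "gaussian":
            lines.append(f"sigma            : {np.sqrt(p.sigma2):.5g}")
        lines.append(f"final objective  : {self.history[-1]['objective']:.6g}")
        viol = self.monotonicity_violations()
        lines.append(f"monotonicity     : {len(viol)} violations in safeguarded stages")
        sd = np.sqrt(np.maximum(np.diag(np.linalg.inv(p.A_hat)), 0))
        lines.append("latent sd (Â^-1) : " + ", ".join(f"{s:.3g}" for s in sd))
        lines.append(f"latent modes rms : {np.sqrt(np.mean(self.latents.Z**2)):.3g}")
        if self.warnings:
            lines.append(f"warnings         : {len(self.warnings)}")
        return "\n".join(lines)

    # -- reconstruction / generation --------------------------------------
    def reconstruct(self, z):
        """(appearance a, velocity v) in template space for a latent code."""
        return reconstruct(self.params, np.asarray(z, dtype=float))

    def render(self, z):
        """Expected subject-space image for a latent code."""
        a, v = self.reconstruct(z)
        defm = geodesic_shoot(v, self.model.ops.Lv, self.config.n_shoot_steps)
        return lk.expected_image(pull(a, defm), self.params.noise)

    def fitted(self, n: int):
        """The model's expected image for training image n."""
        return self.render(self.latents.Z[:, n])

    def sample(self, rng, add_noise=False):
        return inf.sample(
            self.params, self.config, rng, ops=self.model.ops, add_noise=add_noise
        )

    # -- inference ---------------------------------------------------------
    def encode(self, image, n_iter: int = 12) -> inf.Encoding:
        f = self._as_observed(image)
        return inf.encode(f, self.params, self.config, ops=self.model.ops, n_iter=n_iter)

    def impute(self, image, truth=None, n_iter: int = 12):
        f = self._as_observed(image)
        return inf.impute(
            f, self.params, self.config, ops=self.model.ops, n_iter=n_iter, truth=truth
        )

    def _as_observed(self, image):
        if isinstance(image, lk.ObservedImage):
            return image
        return lk.ObservedImage(np.asarray(image, dtype=float), self.params.noise)

    def save(self, path):
        from .imgio import save_checkpoint

        save_checkpoint(path, self.params, self.config)
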