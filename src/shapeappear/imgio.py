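"""Image input/output and model checkpoints.

3D volumes travel as NIfTI (affine preserved, missing voxels as NaN in
float volumes); 2D images as PNG (uint8/16 scaled to [0, 1] on read) or as
raw ``.npy`` arrays, which round-trip bit-exactly including NaN.  A model
checkpoint is a single ``.npz`` container of named arrays plus a JSON echo
of the configuration — no pickled code.
"""

from __future__ import annotations

import json
import os

import numpy as np

from .likelihoods import ObservedImage
from .model import FitConfig, ModelParams
from .operators import GridSpec


def read_image(path, noise: str = "gaussian") -> ObservedImage:
    """Read NIfTI / PNG / npy into an ObservedImage (NaN = missing)."""
    path = os.fspath(path)
    low = path.lower()
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        return ObservedImage(data, noise)
    if low.endswith(".png"):
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse RGB(A) to luminance
            arr = arr[..., :3].mean(axis=-1)
        scale = 65535.0 if arr.dtype == np.uint16 else 255.0
        return ObservedImage(arr.astype(float) / scale, noise)
    if low.endswith(".npy"):
        return ObservedImage(np.load(path, allow_pickle=False), noise)
    raise ValueError(f"unsupported image format: {path}")


def write_image(path, data: np.ndarray, voxel_size=None):
    """Write an array as NIfTI (3D), PNG (2D uint8, NaN as 0) or raw npy."""
    path = os.fspath(path)
    low = path.lower()
    data = np.asarray(data)
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        if voxel_size is not None:
            for i, v in enumerate(voxel_size):
                affine[i, i] = v
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), path)
        return
    if low.endswith(".png"):
        import imageio.v3 as iio

        arr = np.where(np.isfinite(data), data, 0.0)
        arr = np.clip(arr, 0.0, 1.0)
        iio.imwrite(path, (255 * arr).astype(np.uint8))
        return
    if low.endswith(".npy"):
        np.save(path, data, allow_pickle=False)
        return
    raise ValueError(f"unsupported image format: {path}")


def write_deformation(path, deformation, voxel_size=None):
    """Export a deformation's sampled coordinate map as a multi-component
    volume (last axis = component) for visual inspection."""
    write_image(path, deformation.map, voxel_size)


def _config_to_dict(config: FitConfig) -> dict:
    d = dict(config.__dict__)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def save_checkpoint(path, params: ModelParams, config: FitConfig):
    """One portable container: named arrays + config echo (JSON string)."""
    meta = {
        "config": _config_to_dict(config),
        "mode": params.mode,
        "noise": params.noise,
        "dims": list(params.grid.dims),
        "voxel_size": list(params.grid.voxel_size),
    }
    np.savez(
        path,
        mu=params.mu,
        Wa=params.Wa,
        Wv=params.Wv,
        A_hat=params.A_hat,
        sigma2=np.array(params.sigma2),
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_checkpoint(path):
    """Returns (ModelParams, FitConfig)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        cfg_d = meta["config"]
        for k in ("omega_v", "omega_a", "omega_mu"):
            cfg_d[k] = tuple(cfg_d[k])
        if cfg_d.get("mode") != "split":
            cfg_d.pop("Ka", None)
            cfg_d.pop("Kv", None)
        config = FitConfig(**cfg_d)
        grid = GridSpec(tuple(meta["dims"]), tuple(meta["voxel_size"]))
        params = ModelParams(
            grid,
            meta["mode"],
            meta["noise"],
            z["mu"],
            z["Wa"],
            z["Wv"],
            float(z["sigma2"]),
            z["A_hat"],
        )
    return params, config
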