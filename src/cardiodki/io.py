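"""NIfTI serialisation of phantom series and scalar maps.

Complex series are stored as paired real/imaginary volumes; scalar maps embed
the mask as NaN outside.  Gradient tables travel alongside as FSL-style
bval/bvec files (see :mod:`cardiodki.acquisition`).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import read_gradient_table, write_gradient_table
from .phantom import DwiSeries

__all__ = ["save_series", "load_series", "save_scalar_map", "load_scalar_map"]


def _affine(voxel_mm: float) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, 8.0, 1.0])  # 8 mm slice thickness


def _to_nifti_axes(data: np.ndarray) -> np.ndarray:
    # internal order (slice, y, x[, t]) -> NIfTI (x, y, slice[, t])
    return np.moveaxis(data, (0, 1, 2), (2, 1, 0))

def _from_nifti_axes(data: np.ndarray) -> np.ndarray:
    return np.moveaxis(data, (2, 1, 0), (0, 1, 2))


def save_series(series: DwiSeries, prefix: str | Path) -> None:
    """Write ``<prefix>_real.nii.gz`` (+ ``_imag`` if complex), the mask,
    noise frames, gradient table and a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.voxel_mm)
    nib.save(nib.Nifti1Image(_to_nifti_axes(series.data.real), aff),
             f"{prefix}_real.nii.gz")
    if series.is_complex:
        nib.save(nib.Nifti1Image(_to_nifti_axes(series.data.imag), aff),
                 f"{prefix}_imag.nii.gz")
    nib.save(nib.Nifti1Image(
        _to_nifti_axes(series.mask.astype(np.uint8)), aff),
        f"{prefix}_mask.nii.gz")
    if series.noise_frames is not None:
        nib.save(nib.Nifti1Image(
            _to_nifti_axes(series.noise_frames.real), aff),
            f"{prefix}_noise_real.nii.gz")
        if np.iscomplexobj(series.noise_frames):
            nib.save(nib.Nifti1Image(
                _to_nifti_axes(series.noise_frames.imag), aff),
                f"{prefix}_noise_imag.nii.gz")
    write_gradient_table(series.scheme, prefix)
    with open(f"{prefix}_series.json", "w") as f:
        json.dump({"voxel_mm": series.voxel_mm, "sigma": series.sigma,
                   "complex": bool(series.is_complex),
                   "meta": {k: v for k, v in series.meta.items()
                            if isinstance(v, (int, float, str, bool))}},
                  f, indent=2)


def load_series(prefix: str | Path) -> DwiSeries:
    prefix = Path(prefix)
    with open(f"{prefix}_series.json") as f:
        info = json.load(f)
    real = _from_nifti_axes(
        np.asarray(nib.load(f"{prefix}_real.nii.gz").dataobj))
    if info["complex"]:
        imag = _from_nifti_axes(
            np.asarray(nib.load(f"{prefix}_imag.nii.gz").dataobj))
        data = real + 1j * imag
    else:
        data = real
    mask = _from_nifti_axes(
        np.asarray(nib.load(f"{prefix}_mask.nii.gz").dataobj)).astype(bool)
    noise = None
    if Path(f"{prefix}_noise_real.nii.gz").exists():
        noise = _from_nifti_axes(
            np.asarray(nib.load(f"{prefix}_noise_real.nii.gz").dataobj))
        imag_path = Path(f"{prefix}_noise_imag.nii.gz")
        if imag_path.exists():
            noise = noise + 1j * _from_nifti_axes(np.asarray(
                nib.load(imag_path).dataobj))
    scheme = read_gradient_table(prefix)
    return DwiSeries(data, scheme, mask, noise, sigma=info["sigma"],
                     voxel_mm=info["voxel_mm"], meta=info.get("meta", {}))


def save_scalar_map(values: np.ndarray, mask: np.ndarray,
                    path: str | Path, voxel_mm: float = 2.7) -> None:
    """Scalar volume with NaN outside the mask."""
    out = np.where(mask, values, np.nan)
    nib.save(nib.Nifti1Image(_to_nifti_axes(out), _affine(voxel_mm)),
             str(path))


def load_scalar_map(path: str | Path) -> np.ndarray:
    return _from_nifti_axes(np.asarray(nib.load(str(path)).dataobj))
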