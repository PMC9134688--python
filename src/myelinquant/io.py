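"""File-format helpers: NIfTI-1 volumes, FSL bvals/bvecs, TIFF images.

Thin wrappers over nibabel and tifffile that pin the conventions used
throughout the pipeline: DWI as 4-D NIfTI-1 with the affine carried
through untouched, gradient tables in the FSL dialect (one whitespace row
of b-values; three rows of direction components), label masks as integer
NIfTI and stained sections as single-channel TIFF.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from myelinquant.dti import DiffusionScheme

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_scheme_fsl",
    "load_scheme_fsl",
    "save_tiff",
    "load_tiff",
]


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.to_filename(str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def save_scheme_fsl(scheme: DiffusionScheme, bvals_path, bvecs_path) -> None:
    """Write FSL-dialect gradient files: 1 row of b-values, 3 of components."""
    np.savetxt(str(bvals_path), scheme.b_values[None, :], fmt="%.6g")
    np.savetxt(str(bvecs_path), scheme.directions.T, fmt="%.10g")


def load_scheme_fsl(bvals_path, bvecs_path) -> DiffusionScheme:
    b_values = np.loadtxt(str(bvals_path)).ravel()
    directions = np.loadtxt(str(bvecs_path))
    if directions.shape[0] == 3:
        directions = directions.T
    return DiffusionScheme(directions=directions, b_values=b_values)


def save_tiff(image: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def load_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
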