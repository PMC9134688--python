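"""Diffusion-tensor estimation by log-linear least squares.

The single-tensor model relates the diffusion-weighted signal in each voxel
to a symmetric positive tensor ``D`` (mm^2/s)::

    S_i = S0 * exp(-b_i * g_i^T D g_i)

Taking logs makes the model linear in the six distinct tensor elements plus
``ln S0``, so each voxel is fitted by ordinary least squares on the design
matrix built from the gradient scheme.  Eigenvalues of the fitted tensor
give the standard scalar maps: axial diffusivity AD = L1, radial
diffusivity RD = (L2 + L3)/2, mean diffusivity MD = (L1 + L2 + L3)/3 and
fractional anisotropy

    FA = sqrt(3/2) * sqrt(sum (l_i - lbar)^2) / sqrt(sum l_i^2)

which is 0 for isotropic diffusion and 1 for purely one-dimensional
diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IdentifiabilityError",
    "DiffusionScheme",
    "TensorVoxel",
    "TensorFit",
    "ScalarMapSet",
    "design_matrix",
    "fit_tensor",
    "fit_tensor_volume",
    "compute_fa",
    "compute_scalar_maps",
]


class IdentifiabilityError(ValueError):
    """Raised when a gradient scheme cannot identify the six tensor elements."""


@dataclass(frozen=True)
class DiffusionScheme:
    """Gradient directions and b-values defining the forward signal model.

    Parameters
    ----------
    directions : (n, 3) array
        Gradient unit vectors; rows with ``b == 0`` may be zero vectors.
    b_values : (n,) array
        Diffusion weightings in s/mm^2.
    """

    directions: np.ndarray
    b_values: np.ndarray

    def __post_init__(self) -> None:
        directions = np.asarray(self.directions, dtype=float)
        b_values = np.asarray(self.b_values, dtype=float)
        if directions.ndim != 2 or directions.shape[1] != 3:
            raise ValueError("directions must be an (n, 3) array")
        if b_values.shape != (directions.shape[0],):
            raise ValueError("b_values length must match number of directions")
        if np.any(b_values < 0):
            raise ValueError("b-values must be non-negative")
        dwi = b_values > 0
        norms = np.linalg.norm(directions[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("diffusion-weighted directions must be unit norm")
        if dwi.sum() < 6:
            raise IdentifiabilityError(
                "at least 6 diffusion-weighted directions are required"
            )
        if (~dwi).sum() < 1:
            raise ValueError("at least one b=0 acquisition is required")
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "b_values", b_values)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b_values == 0))

    @property
    def n_volumes(self) -> int:
        return int(self.b_values.shape[0])


@dataclass(frozen=True)
class TensorVoxel:
    """Fitted tensor for a single voxel.

    ``D`` is the symmetric 3x3 tensor in mm^2/s, ``eigenvalues`` are sorted
    descending (L1 >= L2 >= L3) and ``residual_rms`` is the RMS log-signal
    residual of the fit.
    """

    D: np.ndarray
    ln_s0: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    residual_rms: float


@dataclass
class TensorFit:
    """Voxel-wise tensor fit over a volume.

    Attributes
    ----------
    D : (..., 3, 3) array
        Fitted tensors.
    eigenvalues : (..., 3) array
        Sorted descending along the last axis.
    ln_s0 : (...) array
    mask : (...) bool array
        False where the fit was not attempted or the voxel was flagged
        invalid (non-finite signals).
    """

    D: np.ndarray
    eigenvalues: np.ndarray
    ln_s0: np.ndarray
    mask: np.ndarray


@dataclass
class ScalarMapSet:
    """FA/MD/AD/RD scalar maps sharing one boolean mask."""

    FA: np.ndarray
    MD: np.ndarray
    AD: np.ndarray
    RD: np.ndarray
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.FA, self.MD, self.AD, self.RD, self.mask)}
        if len(shapes) != 1:
            raise ValueError("all scalar maps must share one shape")


def design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """Build the log-linear design matrix of a gradient scheme.

    Row ``i`` maps the coefficient vector
    ``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0)`` to the log-signal of volume
    ``i``::

        (-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz, 1)

    Raises
    ------
    IdentifiabilityError
        If the matrix has column rank below 7.
    """
    g = np.asarray(scheme.directions, dtype=float)
    b = np.asarray(scheme.b_values, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    X = np.column_stack(
        [
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2.0 * b * gx * gy,
            -2.0 * b * gx * gz,
            -2.0 * b * gy * gz,
            np.ones_like(b),
        ]
    )
    if np.linalg.matrix_rank(X) < 7:
        raise IdentifiabilityError("gradient scheme does not identify the tensor")
    return X


def _clamp_signals(signals: np.ndarray) -> np.ndarray:
    """Replace non-positive signals by a small positive floor.

    The floor is the smallest positive signal in the voxel times 1e-3, so the
    log-linear fit stays defined without distorting valid measurements.
    """
    signals = np.asarray(signals, dtype=float)
    out = signals.copy()
    bad = out <= 0
    if np.any(bad):
        pos = out[out > 0]
        floor = pos.min() * 1e-3 if pos.size else 1e-12
        out[bad] = floor
    return out


def _tensor_from_coefs(coefs: np.ndarray) -> np.ndarray:
    """Assemble symmetric tensors from (..., 7) coefficient arrays."""
    dxx, dyy, dzz, dxy, dxz, dyz = (coefs[..., i] for i in range(6))
    D = np.empty(coefs.shape[:-1] + (3, 3), dtype=float)
    D[..., 0, 0] = dxx
    D[..., 1, 1] = dyy
    D[..., 2, 2] = dzz
    D[..., 0, 1] = D[..., 1, 0] = dxy
    D[..., 0, 2] = D[..., 2, 0] = dxz
    D[..., 1, 2] = D[..., 2, 1] = dyz
    return D


def fit_tensor(signals: np.ndarray, scheme: DiffusionScheme) -> TensorVoxel:
    """Fit the diffusion tensor of one voxel by ordinary least squares.

    Parameters
    ----------
    signals : (n_volumes,) array
        Measured signals in scheme order.  Non-positive values are clamped to
        a small positive floor before taking logs.

    Raises
    ------
    ValueError
        If signals contain non-finite values or have the wrong length.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape != (scheme.n_volumes,):
        raise ValueError("signal vector length must match the scheme")
    if not np.all(np.isfinite(signals)):
        raise ValueError("non-finite signals in voxel")
    X = design_matrix(scheme)
    y = np.log(_clamp_signals(signals))
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    D = _tensor_from_coefs(coefs)
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    resid = y - X @ coefs
    return TensorVoxel(
        D=D,
        ln_s0=float(coefs[6]),
        eigenvalues=evals,
        eigenvectors=evecs,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_tensor_volume(
    dwi: np.ndarray, scheme: DiffusionScheme, mask: np.ndarray | None = None
) -> TensorFit:
    """Fit tensors for every masked voxel of a 4-D DWI volume.

    Parameters
    ----------
    dwi : (X, Y, Z, n_volumes) array
    mask : (X, Y, Z) bool array, optional
        Voxels to fit; defaults to all.  Voxels with non-finite signals are
        excluded from the output mask rather than raising.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[-1] != scheme.n_volumes:
        raise ValueError("dwi must be (X, Y, Z, n_volumes) matching the scheme")
    spatial = dwi.shape[:3]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial:
            raise ValueError("mask shape must match the spatial grid")

    fit_mask = mask & np.all(np.isfinite(dwi), axis=-1)
    flat = dwi[fit_mask]  # (n_vox, n_volumes)
    X = design_matrix(scheme)
    # vectorized signal clamping: per-voxel floor = smallest positive * 1e-3
    clamped = flat.copy()
    if clamped.size:
        pos = np.where(clamped > 0, clamped, np.inf)
        floor = np.where(np.isfinite(pos.min(axis=1)), pos.min(axis=1) * 1e-3, 1e-12)
        bad = clamped <= 0
        clamped[bad] = np.broadcast_to(floor[:, None], clamped.shape)[bad]
    logs = np.log(clamped) if clamped.size else np.empty((0, scheme.n_volumes))
    coefs = np.linalg.lstsq(X, logs.T, rcond=None)[0].T  # (n_vox, 7)
    D_flat = _tensor_from_coefs(coefs)
    evals_flat = np.linalg.eigvalsh(D_flat)[..., ::-1]  # descending

    D = np.zeros(spatial + (3, 3))
    evals = np.zeros(spatial + (3,))
    ln_s0 = np.zeros(spatial)
    D[fit_mask] = D_flat
    evals[fit_mask] = evals_flat
    ln_s0[fit_mask] = coefs[:, 6] if coefs.size else 0.0
    return TensorFit(D=D, eigenvalues=evals, ln_s0=ln_s0, mask=fit_mask)


def compute_fa(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from tensor eigenvalues.

    Negative eigenvalues are clamped to zero before evaluating the closed
    form, keeping FA in [0, 1]; an all-zero eigenvalue triple returns 0 by
    convention.  Works element-wise on (..., 3) arrays.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("eigenvalues must have length 3 on the last axis")
    if not np.all(np.isfinite(lam)):
        raise ValueError("eigenvalues must be finite")
    lam = np.clip(lam, 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam**2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def compute_scalar_maps(fit: TensorFit, mask: np.ndarray | None = None) -> ScalarMapSet:
    """Derive FA/MD/AD/RD maps from a voxel-wise tensor fit.

    AD = L1, RD = (L2 + L3)/2, MD = (L1 + L2 + L3)/3; FA per
    :func:`compute_fa`.  Raw (possibly negative) eigenvalues enter the
    diffusivity maps; the clamping applies to FA only.
    """
    if mask is None:
        mask = fit.mask
    else:
        mask = np.asarray(mask, dtype=bool) & fit.mask
    if not np.any(mask):
        raise ValueError("empty mask: no voxels to summarize")
    lam = fit.eigenvalues
    AD = lam[..., 0].copy()
    RD = (lam[..., 1] + lam[..., 2]) / 2.0
    MD = lam.mean(axis=-1)
    FA = compute_fa(lam)
    for arr in (AD, RD, MD, FA):
        arr[~mask] = 0.0
    return ScalarMapSet(FA=FA, MD=MD, AD=AD, RD=RD, mask=mask)
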