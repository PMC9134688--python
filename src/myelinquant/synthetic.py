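"""Synthetic-data generator for the two-group developmental myelination study.

Every input the pipeline consumes can be generated here with known ground
truth: two-group diffusion tensor phantoms (30-direction scheme, b = 0 and
970 s/mm^2, Rician noise), a developmental MBP concentration table with a
logistic rise in age, four-parameter-logistic ELISA plates, stained-section
images with an exactly constructed positive fraction, and tooth-eruption
count tables.

The phantom places axis-aligned rectangular "tracts" of prolate tensors
(axial > radial diffusivity) inside a partial-volume background: each
background voxel mixes a randomly oriented prolate compartment with the
isotropic compartment at a per-voxel weight drawn uniformly on [0, 1].
That mixing produces the brain-like continuum of FA values — a low-FA
peak with a heavy right tail — that forebrain histograms show in vivo,
instead of an artificial two-spike histogram.  Treatment is modelled as a
per-group radial diffusivity: lowering radial diffusivity in the treated
group raises FA in every voxel with an anisotropic compartment, shifting
the whole histogram rightward, emulating accelerated myelination.
Magnitude-MRI noise is Rician: with independent Gaussian draws
``n1, n2 ~ N(0, sigma)`` and ``sigma = S0 / snr``, the observed signal is
``sqrt((S + n1)^2 + n2^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from myelinquant.dti import DiffusionScheme, compute_fa
from myelinquant.mbp import four_param_logistic

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_scheme",
    "simulate_dwi",
    "simulate_mbp_development",
    "simulate_plate",
    "simulate_ihc_image",
    "simulate_teeth",
    "default_phantom_spec",
]

#: default b0 signal amplitude for phantoms (arbitrary units)
S0 = 1000.0


@dataclass(frozen=True)
class TractRegion:
    """One rectangular tract: integer label, voxel slices, fiber direction."""

    label: int
    name: str
    slices: tuple[slice, slice, slice]
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("tract direction must be nonzero")
        object.__setattr__(self, "direction", d / n)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, diffusivities and group design of a tensor phantom.

    ``tract_radial_diffusivity`` maps group name -> radial diffusivity so a
    treatment effect is expressed as a per-group RD change.  ``snr`` is the
    b0 signal-to-noise ratio; ``np.inf`` disables noise.
    ``partial_volume`` controls whether background voxels mix a randomly
    oriented anisotropic compartment (weight uniform on [0, 1] per voxel,
    fixed across subjects) with the isotropic one; 0 disables mixing and
    leaves the background purely isotropic.
    """

    grid_shape: tuple[int, int, int]
    tract_regions: tuple[TractRegion, ...]
    background_diffusivity: float
    tract_axial_diffusivity: float
    tract_radial_diffusivity: dict[str, float]
    groups: tuple[tuple[str, int], ...]
    snr: float
    seed: int = 0
    partial_volume: float = 1.0

    def __post_init__(self) -> None:
        if self.background_diffusivity <= 0 or self.tract_axial_diffusivity <= 0:
            raise ValueError("diffusivities must be positive")
        for g, rd in self.tract_radial_diffusivity.items():
            if rd <= 0:
                raise ValueError(f"radial diffusivity for group {g!r} must be positive")
            if rd > self.tract_axial_diffusivity:
                raise ValueError("radial diffusivity must not exceed axial")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not (0.0 <= self.partial_volume <= 1.0):
            raise ValueError("partial_volume must lie in [0, 1]")
        grid = self.grid_shape
        for region in self.tract_regions:
            for sl, n in zip(region.slices, grid):
                if sl.start < 0 or sl.stop > n:
                    raise ValueError(f"tract {region.name!r} exceeds the grid")
        names = {g for g, _ in self.groups}
        missing = names - set(self.tract_radial_diffusivity)
        if missing:
            raise ValueError(f"groups without radial diffusivity: {missing}")


@dataclass
class GroundTruth:
    """True tensors, FA and group assignment underlying a simulated study."""

    tensor_field: dict[str, np.ndarray]
    fa_field: dict[str, np.ndarray]
    label_mask: np.ndarray
    group_assignment: dict[str, str]


def make_scheme(
    n_directions: int, b_value: float, n_b0: int = 1, seed: int = 0
) -> DiffusionScheme:
    """Deterministic near-uniform gradient scheme.

    Directions come from the Fibonacci (golden-angle) spiral on the upper
    hemisphere — diffusion weighting only senses axes, so hemisphere
    coverage is the uniform choice and stays well-conditioned down to the
    6-direction identifiability limit.  A seeded random rotation makes
    distinct seeds give distinct but equally uniform direction sets.  The
    b-value vector holds ``n_b0`` zeros followed by ``n_directions``
    copies of ``b_value``.
    """
    if n_directions < 6:
        raise ValueError("tensor estimation needs at least 6 directions")
    if n_b0 < 1:
        raise ValueError("need at least one b=0 volume")
    i = np.arange(n_directions, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = (i + 0.5) / n_directions
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # seeded random rotation keeps the set uniform but seed-dependent
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    dirs = dirs @ Q.T
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    b_values = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    return DiffusionScheme(directions=directions, b_values=b_values)


def _prolate_tensor(direction: np.ndarray, axial: float, radial: float) -> np.ndarray:
    """Cylindrically symmetric tensor with given principal direction."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return radial * np.eye(3) + (axial - radial) * np.outer(d, d)


def _background_mixing(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel partial-volume weights and random fiber directions.

    Drawn once from ``spec.seed`` so the anatomical field is shared by all
    subjects of a study; only the group's radial diffusivity differs.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xB6)))
    w = spec.partial_volume * rng.uniform(0.0, 1.0, size=spec.grid_shape)
    dirs = rng.standard_normal(spec.grid_shape + (3,))
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    return w, dirs


def _group_tensor_field(
    spec: PhantomSpec,
    group: str,
    mixing: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    rd = spec.tract_radial_diffusivity[group]
    iso = spec.background_diffusivity * np.eye(3)
    if spec.partial_volume > 0:
        w, dirs = _background_mixing(spec) if mixing is None else mixing
        aniso = rd * np.eye(3) + (spec.tract_axial_diffusivity - rd) * np.einsum(
            "...i,...j->...ij", dirs, dirs
        )
        D = w[..., None, None] * aniso + (1.0 - w[..., None, None]) * iso
    else:
        D = np.zeros(spec.grid_shape + (3, 3))
        D[...] = iso
    for region in spec.tract_regions:
        D[region.slices] = _prolate_tensor(
            region.direction, spec.tract_axial_diffusivity, rd
        )
    return D


def _label_mask(spec: PhantomSpec) -> np.ndarray:
    mask = np.zeros(spec.grid_shape, dtype=np.int16)
    for region in spec.tract_regions:
        mask[region.slices] = region.label
    return mask


def simulate_dwi(
    spec: PhantomSpec, scheme: DiffusionScheme
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Simulate per-subject DWI volumes from a phantom specification.

    The noiseless forward model is ``S_i = S0 exp(-b_i g_i^T D g_i)``;
    Rician noise with ``sigma = S0 / snr`` is applied per subject (none
    when ``snr`` is infinite).  Output is bit-reproducible for a fixed
    ``spec.seed``.

    Returns
    -------
    volumes : dict subject_id -> (X, Y, Z, n_volumes) array
    truth : GroundTruth
    """
    g = scheme.directions
    b = scheme.b_values
    # quadratic forms g^T D g for all voxels and directions at once
    tensors = {grp: _group_tensor_field(spec, grp) for grp, _ in spec.groups}
    fa_fields = {}
    signals = {}
    for grp, D in tensors.items():
        evals = np.linalg.eigvalsh(D)[..., ::-1]
        fa_fields[grp] = compute_fa(evals)
        q = np.einsum("id,xyzde,ie->xyzi", g, D, g)
        signals[grp] = S0 * np.exp(-b * q)

    rng = np.random.default_rng(spec.seed)
    sigma = 0.0 if np.isinf(spec.snr) else S0 / spec.snr
    volumes: dict[str, np.ndarray] = {}
    assignment: dict[str, str] = {}
    for grp, n_subjects in spec.groups:
        for j in range(n_subjects):
            subject = f"{grp}_{j + 1:02d}"
            assignment[subject] = grp
            clean = signals[grp]
            if sigma == 0.0:
                volumes[subject] = clean.copy()
            else:
                n1 = rng.normal(0.0, sigma, size=clean.shape)
                n2 = rng.normal(0.0, sigma, size=clean.shape)
                volumes[subject] = np.sqrt((clean + n1) ** 2 + n2**2)
    truth = GroundTruth(
        tensor_field=tensors,
        fa_field=fa_fields,
        label_mask=_label_mask(spec),
        group_assignment=assignment,
    )
    return volumes, truth


def default_phantom_spec(
    n_per_group: int = 6,
    snr: float = 25.0,
    rd_vehicle: float = 5.0e-4,
    rd_effect: float = 0.25,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (16, 16, 10),
) -> PhantomSpec:
    """Two-group phantom mirroring the study design.

    Ten rectangular tracts (one per white-matter region label) in an
    isotropic background; the treated group's tract radial diffusivity is
    reduced by ``rd_effect`` (fractional), raising tract FA.
    """
    nx, ny, nz = grid_shape
    names = ("fmi", "gcc", "bcc", "scc", "fmj", "ec", "aca", "ic", "opt", "cp")
    regions = []
    # two columns of five slabs each, along alternating in-plane axes
    n_rows = 5
    for idx, name in enumerate(names):
        col = idx // n_rows
        row = idx % n_rows
        x0 = 1 + col * (nx // 2)
        x1 = x0 + nx // 2 - 2
        y0 = 1 + row * (ny // n_rows)
        y1 = y0 + max(ny // n_rows - 1, 1)
        direction = (1.0, 0.0, 0.0) if idx % 2 == 0 else (0.0, 1.0, 0.0)
        regions.append(
            TractRegion(
                label=idx + 1,
                name=name,
                slices=(slice(x0, x1), slice(y0, y1), slice(2, nz - 2)),
                direction=np.asarray(direction),
            )
        )
    return PhantomSpec(
        grid_shape=grid_shape,
        tract_regions=tuple(regions),
        background_diffusivity=7.0e-4,
        tract_axial_diffusivity=1.2e-3,
        tract_radial_diffusivity={
            "vehicle": rd_vehicle,
            "T4": rd_vehicle * (1.0 - rd_effect),
        },
        groups=(("T4", n_per_group), ("vehicle", n_per_group)),
        snr=snr,
        seed=seed,
    )


def simulate_mbp_development(
    ages,
    groups=("T4", "vehicle"),
    effect: float = 2.0,
    noise_cv: float = 0.15,
    n_per_cell: int = 6,
    seed: int = 0,
    plateau: float = 100.0,
    midpoint: float = 8.5,
    scale: float = 1.5,
) -> pd.DataFrame:
    """Developmental MBP concentration table with a logistic rise in age.

    The mean curve is ``plateau / (1 + exp(-(age - m) / scale))`` with the
    treated group's midpoint ``m`` shifted earlier by ``effect`` days
    (treatment accelerates the rise).  Noise is multiplicative Gaussian
    with coefficient of variation ``noise_cv``; values are floored at 0.

    Returns a table with columns subject, group, pnd, mbp_ng_ml.
    """
    ages = [int(a) for a in ages]
    if any(a < 3 or a > 11 for a in ages):
        raise ValueError("ages must lie within postnatal days 3..11")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    treated = groups[0]
    rng = np.random.default_rng(seed)
    rows = []
    for age in ages:
        for grp in groups:
            m = midpoint - effect if grp == treated else midpoint
            mean = plateau / (1.0 + np.exp(-(age - m) / scale))
            for j in range(n_per_cell):
                noise = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
                value = max(mean * (1.0 + noise), 0.0)
                rows.append(
                    {
                        "subject": f"{grp}_p{age}_{j + 1:02d}",
                        "group": grp,
                        "pnd": age,
                        "mbp_ng_ml": value,
                    }
                )
    return pd.DataFrame(rows)


def mbp_mean_curve(
    age,
    group: str,
    treated_group: str = "T4",
    effect: float = 2.0,
    plateau: float = 100.0,
    midpoint: float = 8.5,
    scale: float = 1.5,
):
    """Noise-free logistic mean of the developmental MBP curve."""
    m = midpoint - effect if group == treated_group else midpoint
    return plateau / (1.0 + np.exp(-(np.asarray(age, dtype=float) - m) / scale))


def simulate_plate(
    standard_top: float = 100.0,
    n_serial: int = 7,
    dilution_factor: float = 2.0,
    curve_params: tuple[float, float, float, float] = (0.05, 2.0, 10.0, 1.0),
    noise_cv: float = 0.0,
    samples=(),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate an ELISA plate as well-level CSV records.

    Standards form a ``dilution_factor``-fold series from ``standard_top``
    (``n_serial`` points) plus a blank; signals come from the 4PL
    ``curve_params = (lower, upper, ec50, slope)`` with multiplicative
    Gaussian noise of CV ``noise_cv``.  ``samples`` are
    (sample_id, true neat ng/mL, dilution factor) triples measured at
    their diluted concentration.

    Returns a table with columns well, kind, sample_id, nominal_ng_ml,
    dilution, signal.
    """
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    lower, upper, ec50, slope = (float(v) for v in curve_params)
    if slope == 0:
        raise ValueError("curve slope must be nonzero")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    rng = np.random.default_rng(seed)

    def noisy(signal: float) -> float:
        if noise_cv == 0:
            return signal
        return signal * max(1.0 + rng.normal(0.0, noise_cv), 0.0)

    rows = []
    well = 1
    for j in range(n_serial):
        conc = standard_top / dilution_factor**j
        sig = float(four_param_logistic(conc, lower, upper, ec50, slope))
        rows.append(
            {
                "well": f"W{well:02d}",
                "kind": "standard",
                "sample_id": "",
                "nominal_ng_ml": conc,
                "dilution": 1.0,
                "signal": noisy(sig),
            }
        )
        well += 1
    rows.append(
        {
            "well": f"W{well:02d}",
            "kind": "blank",
            "sample_id": "",
            "nominal_ng_ml": 0.0,
            "dilution": 1.0,
            "signal": noisy(lower),
        }
    )
    well += 1
    for sample_id, true_neat, dilution in samples:
        diluted = float(true_neat) / float(dilution)
        sig = float(four_param_logistic(diluted, lower, upper, ec50, slope))
        rows.append(
            {
                "well": f"W{well:02d}",
                "kind": "sample",
                "sample_id": str(sample_id),
                "nominal_ng_ml": np.nan,
                "dilution": float(dilution),
                "signal": noisy(sig),
            }
        )
        well += 1
    return pd.DataFrame(rows)


def simulate_ihc_image(
    shape: tuple[int, int] = (128, 128),
    positive_fraction: float = 0.25,
    fg_intensity: float = 200.0,
    bg_intensity: float = 50.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Stained-section image with an exactly constructed positive fraction.

    The hemisphere mask is the inscribed ellipse of the frame; exactly
    ``round(positive_fraction * mask_area)`` mask pixels (a seeded random
    subset) are drawn at the foreground intensity, the rest at background,
    then Gaussian noise of SD ``noise_sd`` is added everywhere.

    Returns ``(image, mask, realized_fraction)`` where the realized
    fraction is the exact constructed pixel fraction.
    """
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError("positive_fraction must lie in [0, 1]")
    if fg_intensity <= bg_intensity:
        raise ValueError("foreground intensity must exceed background")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2 <= 1.0
    n_mask = int(mask.sum())
    n_pos = int(round(positive_fraction * n_mask))
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_mask, size=n_pos, replace=False)
    flat_positive = np.zeros(n_mask, dtype=bool)
    flat_positive[idx] = True
    image = np.full(shape, bg_intensity, dtype=float)
    vals = np.full(n_mask, bg_intensity, dtype=float)
    vals[flat_positive] = fg_intensity
    image[mask] = vals
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image, mask, n_pos / n_mask


def simulate_teeth(
    n_per_group: int,
    p_eruption_by_group: tuple[float, float],
    seed: int = 0,
) -> np.ndarray:
    """Tooth-eruption 2x2 count table: rows = groups, cols = (erupted, not).

    Pups erupt independently with their group's probability; fixed seed
    gives a reproducible table.
    """
    p1, p2 = p_eruption_by_group
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("eruption probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    e1 = int(rng.binomial(n_per_group, p1))
    e2 = int(rng.binomial(n_per_group, p2))
    return np.array([[e1, n_per_group - e1], [e2, n_per_group - e2]], dtype=int)
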