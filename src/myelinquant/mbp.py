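"""MBP quantification: ELISA standard-curve back-calculation and IHC scoring.

The ELISA side fits a four-parameter logistic (4PL) standard curve to
blank-subtracted signals of a purified-protein dilution series,

    y(x) = lower + (upper - lower) / (1 + (x / ec50)^(-slope)),

inverts it to back-calculate sample concentrations, scales by dilution
factor, and evaluates the usual assay-acceptance metrics: a lower limit of
quantification (LLOQ; the lowest standard back-calculated within the
70-120 % acceptance band), spike-and-recovery percentages, and
dilution-linearity percentages, each flagged against the same 70-120 %
band.

The IHC side classifies pixels of a stained section as MBP-positive when
their absolute deviation from the background level exceeds a threshold,
and reports the percentage of the hemisphere mask occupied by positive
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "PlateModel",
    "SampleQuant",
    "RecoveryReport",
    "AreaFractionResult",
    "four_param_logistic",
    "inverse_four_param_logistic",
    "fit_standard_curve",
    "quantify",
    "spike_recovery",
    "dilution_linearity",
    "percent_positive_area",
    "suggest_threshold",
]

ACCEPTANCE_LOW = 70.0
ACCEPTANCE_HIGH = 120.0


def four_param_logistic(conc, lower: float, upper: float, ec50: float, slope: float):
    """4PL response; approaches ``lower`` at zero and ``upper`` at saturation."""
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(conc > 0, (conc / ec50) ** (-slope), np.inf)
    return lower + (upper - lower) / (1.0 + ratio)


def inverse_four_param_logistic(
    signal, lower: float, upper: float, ec50: float, slope: float
):
    """Invert the 4PL over its open response range (lower, upper)."""
    y = np.asarray(signal, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (upper - lower) / (y - lower) - 1.0
        conc = ec50 * frac ** (-1.0 / slope)
    return np.where((y > lower) & (y < upper), conc, np.nan)


@dataclass
class PlateModel:
    """Fitted ELISA standard curve with acceptance metrics.

    ``standards`` holds (nominal ng/mL, blank-subtracted signal) pairs;
    ``lloq`` is in ng/mL, ``None`` when no standard passes back-calculation
    within the acceptance band.
    """

    lower: float
    upper: float
    ec50: float
    slope: float
    standards: pd.DataFrame
    blank_signal: float
    lloq: float | None
    residuals: np.ndarray = field(repr=False)

    def predict(self, conc):
        return four_param_logistic(conc, self.lower, self.upper, self.ec50, self.slope)

    def invert(self, signal):
        return inverse_four_param_logistic(
            signal, self.lower, self.upper, self.ec50, self.slope
        )


@dataclass(frozen=True)
class SampleQuant:
    sample_id: str
    signal: float
    diluted_conc: float
    dilution: float
    neat_conc: float
    in_range: bool
    flag: str = ""


@dataclass
class RecoveryReport:
    """Spike recoveries and dilution-linearity percentages with pass flags."""

    spike_recoveries: pd.DataFrame
    linearity: pd.DataFrame


@dataclass(frozen=True)
class AreaFractionResult:
    subject_id: str
    positive_pixels: int
    mask_pixels: int
    percent_positive: float
    pnd: int | None = None
    group: str = ""


def fit_standard_curve(
    standards,
    blank: float = 0.0,
    monotone_tol: float = 0.25,
) -> PlateModel:
    """Fit a 4PL standard curve by least squares on blank-subtracted signals.

    Parameters
    ----------
    standards : sequence of (nominal ng/mL, raw signal)
        At least 5 nonzero standards.
    blank : float
        Blank-well signal subtracted from every standard.
    monotone_tol : float
        Maximum tolerated fractional decrease between consecutive standards
        before the curve is rejected as non-monotone.

    The LLOQ is the lowest standard whose back-calculated concentration
    recovers its nominal within the 70-120 % acceptance band.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("standards must be (nominal, signal) pairs")
    nominal = arr[:, 0]
    sig = arr[:, 1] - blank
    keep = nominal > 0
    if keep.sum() < 5:
        raise ValueError("need at least 5 nonzero standards")
    nominal, sig = nominal[keep], sig[keep]
    order = np.argsort(nominal)
    nominal, sig = nominal[order], sig[order]
    span = sig.max() - sig.min()
    drops = np.diff(sig)
    if span > 0 and np.any(drops < -monotone_tol * span):
        raise ValueError("standard signals are not monotone in concentration")

    upper0 = sig.max() * 1.05 + 1e-9
    lower0 = max(sig.min() * 0.5, 0.0)
    ec50_0 = float(np.interp(0.5 * (sig.min() + sig.max()), sig, nominal))
    p0 = [lower0, upper0, max(ec50_0, nominal.min()), 1.0]
    popt, _ = optimize.curve_fit(
        four_param_logistic,
        nominal,
        sig,
        p0=p0,
        maxfev=20000,
        bounds=([-np.inf, 0.0, 1e-9, 1e-3], [np.inf, np.inf, np.inf, 50.0]),
    )
    lower, upper, ec50, slope = (float(v) for v in popt)
    resid = sig - four_param_logistic(nominal, *popt)

    back = inverse_four_param_logistic(sig, lower, upper, ec50, slope)
    with np.errstate(invalid="ignore"):
        recovery = back / nominal * 100.0
    passing = np.isfinite(recovery) & (recovery >= ACCEPTANCE_LOW) & (recovery <= ACCEPTANCE_HIGH)
    lloq = float(nominal[passing].min()) if passing.any() else None

    table = pd.DataFrame(
        {
            "nominal_ng_ml": nominal,
            "signal": sig,
            "back_calculated": back,
            "recovery_pct": recovery,
            "passes": passing,
        }
    )
    return PlateModel(
        lower=lower,
        upper=upper,
        ec50=ec50,
        slope=slope,
        standards=table,
        blank_signal=float(blank),
        lloq=lloq,
        residuals=resid,
    )


def quantify(samples, model: PlateModel) -> list[SampleQuant]:
    """Back-calculate sample concentrations from a fitted plate model.

    Parameters
    ----------
    samples : sequence of (sample_id, raw signal, dilution factor)

    Signals outside the invertible response range are flagged
    (``"saturated"`` above the upper asymptote, ``"below_lloq"`` under the
    LLOQ or below the lower asymptote) and never extrapolated.
    """
    out: list[SampleQuant] = []
    for sample_id, signal, dilution in samples:
        y = float(signal) - model.blank_signal
        diluted = float(model.invert(y))
        flag = ""
        if y >= model.upper:
            flag = "saturated"
        elif not np.isfinite(diluted):
            flag = "below_lloq"
        elif model.lloq is not None and diluted < model.lloq:
            flag = "below_lloq"
        neat = diluted * float(dilution) if np.isfinite(diluted) else np.nan
        out.append(
            SampleQuant(
                sample_id=str(sample_id),
                signal=float(signal),
                diluted_conc=diluted,
                dilution=float(dilution),
                neat_conc=neat,
                in_range=flag == "",
                flag=flag,
            )
        )
    return out


def spike_recovery(base_measured: float, spiked_measured: float, spike_nominal: float):
    """Percent recovery of a known spike: (spiked - base) / nominal * 100.

    Returns ``(percent, passes)`` where ``passes`` applies the 70-120 %
    acceptance band.  Negative recoveries are reported as-is with a fail
    flag.
    """
    if spike_nominal <= 0:
        raise ValueError("spike_nominal must be positive")
    pct = (spiked_measured - base_measured) / spike_nominal * 100.0
    return float(pct), bool(ACCEPTANCE_LOW <= pct <= ACCEPTANCE_HIGH)


def dilution_linearity(series) -> pd.DataFrame:
    """Dilution-linearity percentages relative to the least-diluted step.

    Parameters
    ----------
    series : sequence of (dilution factor, neat estimate ng/mL)

    Each step's neat estimate is divided by the reference (smallest
    dilution) estimate; values are flagged against the 70-120 % band.
    """
    arr = sorted(((float(d), float(v)) for d, v in series), key=lambda t: t[0])
    if len(arr) < 2:
        raise ValueError("need at least 2 dilutions")
    ref = arr[0][1]
    if ref <= 0:
        raise ValueError("reference estimate must be positive")
    rows = []
    for d, v in arr:
        pct = v / ref * 100.0
        rows.append(
            {
                "dilution": d,
                "neat_estimate": v,
                "linearity_pct": pct,
                "passes": ACCEPTANCE_LOW <= pct <= ACCEPTANCE_HIGH,
            }
        )
    return pd.DataFrame(rows)


def percent_positive_area(
    image: np.ndarray,
    hemisphere_mask: np.ndarray,
    background_value: float,
    threshold: float,
    subject_id: str = "",
    pnd: int | None = None,
    group: str = "",
) -> AreaFractionResult:
    """Percent of the hemisphere mask occupied by stain-positive pixels.

    A pixel is positive when ``|pixel - background_value| > threshold``
    within the mask.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(hemisphere_mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("empty hemisphere mask")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    positive = np.abs(image - background_value) > threshold
    n_pos = int(np.count_nonzero(positive & mask))
    n_mask = int(mask.sum())
    return AreaFractionResult(
        subject_id=subject_id,
        positive_pixels=n_pos,
        mask_pixels=n_mask,
        percent_positive=100.0 * n_pos / n_mask,
        pnd=pnd,
        group=group,
    )


def suggest_threshold(image: np.ndarray, hemisphere_mask: np.ndarray, background_value: float) -> float:
    """Default IHC threshold: Otsu split of masked |pixel - background|.

    Separates the background and foreground intensity modes when the
    instrument's own threshold setting is unavailable.
    """
    from skimage.filters import threshold_otsu

    dev = np.abs(np.asarray(image, dtype=float) - background_value)
    vals = dev[np.asarray(hemisphere_mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty hemisphere mask")
    if vals.max() == vals.min():
        return 0.0
    return float(threshold_otsu(vals))
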