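"""Effective vascular permeability from intermittent extravasation traces.

After an intravenous bolus of FITC-labeled albumin, the mean fluorescence
intensity of the imaged field rises approximately linearly over the ~10-minute
recording as tracer leaks across the vessel wall into the interstitium, while
plasma clearance slowly removes tracer from the circulation.  The effective
permeability ``P`` (cm/s) is recovered from the normalized slope of that ramp,

    P = (1 - HT) * (V/S) * ( (dI/dt) / (I0 - Ib) + 1/K )

where ``HT`` is the average microvessel hematocrit (tracer is confined to
plasma), ``V/S`` is the volume-to-surface ratio of the perfused vasculature in
the imaged tissue, ``I0`` is the intensity immediately after the vessels fill,
``Ib`` the pre-injection background, and ``K`` the time constant of albumin
plasma clearance.  ``V/S`` is carried in micrometres internally; the returned
``P`` is converted to cm/s (1 um/s = 1e-4 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .errors import GeometryError, InsufficientDataError

__all__ = [
    "DEFAULT_HEMATOCRIT",
    "DEFAULT_CLEARANCE_S",
    "PermeabilityTrace",
    "PermeabilityResult",
    "fit_slope",
    "estimate_permeability",
    "vs_ratio_from_geometry",
    "infer_reference_intensities",
]

UM_PER_S_TO_CM_PER_S = 1e-4

#: Average microvessel hematocrit assumed for plasma-borne tracer.
DEFAULT_HEMATOCRIT = 0.19

#: Time constant of albumin plasma clearance, seconds.
DEFAULT_CLEARANCE_S = 9.1e3


@dataclass
class PermeabilityTrace:
    """Intermittent intensity-time samples plus the constants of the model.

    Attributes
    ----------
    times_s : sample times in seconds, strictly increasing (~600 s span).
    intensities : mean fluorescence intensity of the whole image per sample.
    I0 : intensity immediately after filling of all vessels by the tracer.
    Ib : background intensity before injection.
    vs_ratio_um : vessel volume-to-surface ratio V/S in micrometres.
    hematocrit : tube hematocrit fraction, default 0.19.
    clearance_s : plasma clearance time constant K in seconds, default 9.1e3.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    I0: float
    Ib: float
    vs_ratio_um: float
    hematocrit: float = DEFAULT_HEMATOCRIT
    clearance_s: float = DEFAULT_CLEARANCE_S

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same shape")
        if self.times_s.size < 3:
            raise InsufficientDataError(
                f"need at least 3 samples, got {self.times_s.size}"
            )
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not self.I0 > self.Ib:
            raise ValueError(f"I0 ({self.I0}) must exceed Ib ({self.Ib})")
        # HT = 1 is allowed as the degenerate all-cell limit (P identically 0)
        if not 0.0 <= self.hematocrit <= 1.0:
            raise ValueError("hematocrit must lie in [0, 1]")
        if self.clearance_s <= 0 or self.vs_ratio_um <= 0:
            raise ValueError("clearance constant and V/S ratio must be positive")


@dataclass
class PermeabilityResult:
    """Permeability estimate with its slope fit and quality flags."""

    P_cm_per_s: float
    slope_per_s: float          # dI/dt, intensity units per second
    slope_se: float             # OLS standard error of the slope
    residual_sd: float
    n_samples: int
    negative_P: bool = field(default=False)

    @property
    def flags(self) -> list[str]:
        return ["negative_permeability"] if self.negative_P else []


def fit_slope(trace: PermeabilityTrace) -> tuple[float, float, float]:
    """Ordinary least-squares slope of intensity against time.

    Returns ``(slope, slope_se, residual_sd)`` over the full sampling window.
    """
    t, y = trace.times_s, trace.intensities
    if t.size < 3:
        raise InsufficientDataError("slope fit needs at least 3 samples")
    res = _sps.linregress(t, y)
    fitted = res.intercept + res.slope * t
    residual_sd = float(np.std(y - fitted, ddof=2)) if t.size > 2 else 0.0
    return float(res.slope), float(res.stderr), residual_sd


def estimate_permeability(trace: PermeabilityTrace) -> PermeabilityResult:
    """Estimate effective vascular permeability P (cm/s) from a trace.

    A negative computed P (possible with noisy, flat traces) is reported
    with ``negative_P=True`` rather than clipped.
    """
    if trace.I0 == trace.Ib:
        raise ZeroDivisionError("I0 equals Ib; normalized slope undefined")
    slope, slope_se, resid_sd = fit_slope(trace)
    p_um_s = (1.0 - trace.hematocrit) * trace.vs_ratio_um * (
        slope / (trace.I0 - trace.Ib) + 1.0 / trace.clearance_s
    )
    p_cm_s = p_um_s * UM_PER_S_TO_CM_PER_S
    return PermeabilityResult(
        P_cm_per_s=float(p_cm_s),
        slope_per_s=slope,
        slope_se=slope_se,
        residual_sd=resid_sd,
        n_samples=trace.times_s.size,
        negative_P=bool(p_cm_s < 0),
    )


def vs_ratio_from_geometry(segments) -> float:
    """Vessel volume-to-surface ratio V/S (um) from measured segments.

    Each segment is modeled as a cylinder of its measured diameter and length:
    ``V/S = sum(pi (D_i/2)^2 L_i) / sum(pi D_i L_i)``, which reduces to D/4
    when all diameters are equal.  Accepts any iterable of objects with
    ``diameter_um`` and ``length_um`` attributes (e.g. VesselSegment).
    """
    diams = np.array([s.diameter_um for s in segments], dtype=float)
    lengths = np.array([s.length_um for s in segments], dtype=float)
    if diams.size == 0:
        raise GeometryError("V/S ratio needs at least one segment")
    if np.any(diams <= 0) or np.any(lengths <= 0):
        raise GeometryError("segments must have positive diameter and length")
    volume = np.sum(np.pi * (diams / 2.0) ** 2 * lengths)
    surface = np.sum(np.pi * diams * lengths)
    return float(volume / surface)


def infer_reference_intensities(
    times_s: np.ndarray,
    intensities: np.ndarray,
    pre_injection: float | None = None,
) -> tuple[float, float]:
    """Derive (I0, Ib) from a raw trace when not recorded separately.

    I0 is the maximum of the first three samples (the vessels are filled
    within the first readings); Ib is the pre-injection value when available,
    else the 1st percentile of the trace.
    """
    y = np.asarray(intensities, dtype=float)
    if y.size < 3:
        raise InsufficientDataError("need at least 3 samples to infer I0")
    i0 = float(np.max(y[:3]))
    ib = float(pre_injection) if pre_injection is not None else float(
        np.percentile(y, 1)
    )
    return i0, ib
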