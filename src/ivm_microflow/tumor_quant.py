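"""Tumor area, relative growth, take rate and protocol bookkeeping.

Tumor extent is read from the mCherry channel at low magnification.  Each
engrafted animal is imaged weekly (days 7/14/21); its growth is expressed
relative to its own day-7 area (day 7 = 100%).  Cohort summaries report the
take rate (engrafted / implanted), per-day mean +/- SD of relative area, and
the per-day n, which shrinks when femur fracture ends observation early.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import CalibrationError, InsufficientDataError

__all__ = [
    "TumorObservation",
    "CohortResult",
    "segment_tumor_area",
    "relative_growth",
    "take_rate",
    "apply_protocol_rules",
    "summarize_cohort",
    "observations_to_frame",
]

STATUS_ENGRAFTED = "engrafted"
STATUS_NO_ENGRAFTMENT = "excluded_no_engraftment"
STATUS_INFECTION = "excluded_infection"
STATUS_FRACTURE = "censored_fracture"

_EXCLUDED = {STATUS_NO_ENGRAFTMENT, STATUS_INFECTION}


@dataclass(frozen=True)
class TumorObservation:
    """One animal on one observation day."""

    animal_id: str
    tissue: str              # "FW" (bone) or "DSC" (striated muscle)
    cell_line: str           # LnCap | Du145 | Pc3
    day: int
    area_mm2: float          # NaN for excluded animals
    relative_area_pct: float | None = None   # day 7 == 100 once filled
    status: str = STATUS_ENGRAFTED

    @property
    def excluded(self) -> bool:
        return self.status in _EXCLUDED


@dataclass
class CohortResult:
    """Per-(tissue, cell line) take rate and growth summary."""

    tissue: str
    cell_line: str
    n_implanted: int
    n_engrafted: int
    take_rate_pct: int                    # rounded, as reported
    take_rate_exact: float
    mean_relative_by_day: dict[int, float]
    sd_relative_by_day: dict[int, float]
    n_by_day: dict[int, int]
    mean_area_by_day: dict[int, float] = field(default_factory=dict)


def segment_tumor_area(image: np.ndarray, pixel_size_um: float) -> float:
    """Tumor area (mm^2) of the largest bright component in one frame.

    Otsu threshold on the tumor channel, hole filling, largest connected
    component, pixel count converted via pixel_size^2.  A frame with no
    separable foreground (blank or pure noise) returns 0 with a warning.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise CalibrationError("pixel size must be a positive um/pixel value")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D frame")
    span = float(img.max() - img.min())
    if span <= 0:
        warnings.warn("blank frame: no tumor signal", stacklevel=2)
        return 0.0
    thr = threshold_otsu(img)
    mask = img > thr
    if not mask.any() or mask.all():
        warnings.warn("threshold found no separable object", stacklevel=2)
        return 0.0
    # reject frames where the "object" is indistinguishable from noise
    fg_mean, bg = img[mask].mean(), img[~mask]
    if fg_mean - bg.mean() < 4.0 * max(bg.std(), 1e-12):
        warnings.warn("no object above the noise floor", stacklevel=2)
        return 0.0
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n == 0:
        return 0.0
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    n_px = int(np.sum(labels == largest))
    return n_px * (pixel_size_um ** 2) * 1e-6  # um^2 -> mm^2


def relative_growth(series: list[TumorObservation]) -> list[TumorObservation]:
    """Fill ``relative_area_pct`` for one animal's series (day 7 = 100%).

    Requires a positive day-7 area as the per-animal baseline.
    """
    baseline = [o for o in series if o.day == 7 and np.isfinite(o.area_mm2)]
    if not baseline or baseline[0].area_mm2 <= 0:
        raise InsufficientDataError(
            "relative growth undefined without a positive day-7 area"
        )
    a7 = baseline[0].area_mm2
    return [
        replace(o, relative_area_pct=100.0 * o.area_mm2 / a7)
        if np.isfinite(o.area_mm2)
        else o
        for o in series
    ]


def take_rate(n_implanted: int, n_engrafted: int) -> tuple[int, float]:
    """Take rate as (rounded integer percent, exact percent).

    The integer form matches how engraftment rates are conventionally
    reported; the exact fraction is retained for computation.
    """
    if n_implanted <= 0:
        raise ValueError("take rate undefined for zero implanted animals")
    if not 0 <= n_engrafted <= n_implanted:
        raise ValueError("need 0 <= n_engrafted <= n_implanted")
    exact = 100.0 * n_engrafted / n_implanted
    return int(round(exact)), exact


def apply_protocol_rules(
    observations: list[TumorObservation],
) -> tuple[list[TumorObservation], list[str]]:
    """Apply the exclusion/censoring rules; return kept records + audit log.

    * Animals without day-7 engraftment, or with postoperative infection, are
      excluded from growth statistics (they still count in the take-rate
      denominator, which is handled by :func:`summarize_cohort`).
    * Fracture-censored animals keep every record up to their last observed
      day; nothing is imputed afterwards.
    """
    kept: list[TumorObservation] = []
    audit: list[str] = []
    by_animal: dict[str, list[TumorObservation]] = {}
    for o in observations:
        by_animal.setdefault(o.animal_id, []).append(o)
    for animal_id, series in by_animal.items():
        statuses = {o.status for o in series}
        if STATUS_NO_ENGRAFTMENT in statuses:
            audit.append(f"{animal_id}: excluded (no engraftment on day 7)")
            continue
        if STATUS_INFECTION in statuses:
            audit.append(f"{animal_id}: excluded (postoperative infection)")
            continue
        if STATUS_FRACTURE in statuses:
            last = max(o.day for o in series)
            audit.append(
                f"{animal_id}: censored by femur fracture after day {last}"
            )
        kept.extend(sorted(series, key=lambda o: o.day))
    return kept, audit


def observations_to_frame(observations: list[TumorObservation]) -> pd.DataFrame:
    """Long-format table of observations (one row per animal-day)."""
    return pd.DataFrame(
        {
            "animal_id": [o.animal_id for o in observations],
            "tissue": [o.tissue for o in observations],
            "cell_line": [o.cell_line for o in observations],
            "day": [o.day for o in observations],
            "area_mm2": [o.area_mm2 for o in observations],
            "relative_area_pct": [o.relative_area_pct for o in observations],
            "status": [o.status for o in observations],
        }
    )


def summarize_cohort(
    observations: list[TumorObservation],
    n_implanted: int | None = None,
) -> CohortResult:
    """Cohort take rate and per-day growth summary for one tissue/cell line.

    Relative growth is computed per animal and then averaged (each tumor is
    normalized to its own day-7 area).  Excluded animals appear in the
    take-rate denominator only.
    """
    if not observations:
        raise InsufficientDataError("empty cohort")
    tissues = {o.tissue for o in observations}
    lines = {o.cell_line for o in observations}
    if len(tissues) != 1 or len(lines) != 1:
        raise ValueError("summarize_cohort expects a single tissue/cell line")
    animals = {o.animal_id for o in observations}
    excluded = {o.animal_id for o in observations if o.excluded}
    no_engraft = {
        o.animal_id for o in observations if o.status == STATUS_NO_ENGRAFTMENT
    }
    n_impl = n_implanted if n_implanted is not None else len(animals)
    n_engrafted = len(animals) - len(no_engraft)
    rate_int, rate_exact = take_rate(n_impl, n_engrafted)

    kept, _ = apply_protocol_rules(observations)
    by_animal: dict[str, list[TumorObservation]] = {}
    for o in kept:
        by_animal.setdefault(o.animal_id, []).append(o)
    filled: list[TumorObservation] = []
    for series in by_animal.values():
        filled.extend(relative_growth(series))

    days = sorted({o.day for o in filled})
    mean_rel, sd_rel, n_day, mean_area = {}, {}, {}, {}
    for d in days:
        vals = np.array(
            [o.relative_area_pct for o in filled if o.day == d], dtype=float
        )
        areas = np.array([o.area_mm2 for o in filled if o.day == d], dtype=float)
        n_day[d] = int(vals.size)
        mean_rel[d] = float(vals.mean()) if vals.size else math.nan
        sd_rel[d] = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
        mean_area[d] = float(areas.mean()) if areas.size else math.nan

    return CohortResult(
        tissue=tissues.pop(),
        cell_line=lines.pop(),
        n_implanted=n_impl,
        n_engrafted=n_engrafted,
        take_rate_pct=rate_int,
        take_rate_exact=rate_exact,
        mean_relative_by_day=mean_rel,
        sd_relative_by_day=sd_rel,
        n_by_day=n_day,
        mean_area_by_day=mean_area,
    )
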