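"""Scalar assay metrics: wound closure, relative-to-control ratios,
tumor volume / fold change, and percent-positive-cell scoring.

Pure functions on measured areas, counts and calliper dimensions; image
acquisition and segmentation happen upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import DomainError

__all__ = [
    "WoundMeasurement",
    "TumorMeasurement",
    "wound_closure_pct",
    "relative_to_control",
    "tumor_volume",
    "volume_fold_change",
    "percent_positive_cells",
    "WOUND_GAP_GUIDANCE_MM",
]

#: Recommended initial scratch-gap width range (mm); outside it a warning fires.
WOUND_GAP_GUIDANCE_MM = (0.60, 0.75)


@dataclass(frozen=True)
class WoundMeasurement:
    """Scratch-assay gap areas at 0 h (t1) and endpoint (t2), same units.

    ``gap_width_mm`` is optional metadata; when given, values outside the
    0.60–0.75 mm guidance raise a UserWarning at construction.
    """

    area_t1: float
    area_t2: float
    gap_width_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.area_t1 > 0:
            raise DomainError(f"initial gap area must be positive, got {self.area_t1}")
        if self.area_t2 < 0:
            raise DomainError(f"endpoint gap area must be non-negative, got {self.area_t2}")
        if self.gap_width_mm is not None:
            lo, hi = WOUND_GAP_GUIDANCE_MM
            if not lo <= self.gap_width_mm <= hi:
                warnings.warn(
                    f"initial wound gap {self.gap_width_mm:.2f} mm outside the "
                    f"{lo:.2f}-{hi:.2f} mm guidance", UserWarning, stacklevel=3)


@dataclass(frozen=True)
class TumorMeasurement:
    """Calliper length/width (mm) with derived modified-ellipsoid volume."""

    length: float
    width: float
    baseline_volume: float | None = None

    @property
    def volume(self) -> float:
        return tumor_volume(self.length, self.width)

    @property
    def fold_change(self) -> float:
        if self.baseline_volume is None:
            raise DomainError("baseline_volume not set")
        return volume_fold_change(self.volume, self.baseline_volume)


def wound_closure_pct(m: WoundMeasurement) -> float:
    """(area_t1 − area_t2) / area_t1 × 100; negative when the gap widened."""
    return (m.area_t1 - m.area_t2) / m.area_t1 * 100.0


def relative_to_control(treated: float, control: float) -> float:
    """treated / control (invasion counts, fluorescence, colony counts…)."""
    if not control > 0:
        raise DomainError(f"control must be positive, got {control}")
    if treated < 0:
        raise DomainError(f"treated measurement must be non-negative, got {treated}")
    return treated / control


def tumor_volume(length: float, width: float) -> float:
    """Modified ellipsoidal volume length × width² / 2 (mm³).

    Length is the larger calliper dimension by convention; swapped inputs
    are corrected with a warning.
    """
    if not (length > 0 and width > 0):
        raise DomainError(f"dimensions must be positive, got ({length}, {width})")
    if width > length:
        warnings.warn("width > length; swapping to enforce length >= width",
                      UserWarning, stacklevel=2)
        length, width = width, length
    return length * width * width / 2.0


def volume_fold_change(current: float, baseline: float) -> float:
    """current / baseline tumor volume (baseline is an explicit input)."""
    if not baseline > 0:
        raise DomainError(f"baseline volume must be positive, got {baseline}")
    if current < 0:
        raise DomainError(f"current volume must be non-negative, got {current}")
    return current / baseline


def percent_positive_cells(positive: int, total: int) -> float:
    """100 × positive / total stained cells."""
    if total <= 0:
        raise DomainError(f"total count must be positive, got {total}")
    if not 0 <= positive <= total:
        raise DomainError(f"positive count {positive} outside [0, {total}]")
    return 100.0 * positive / total
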