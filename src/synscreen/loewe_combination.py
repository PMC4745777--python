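"""Loewe-additivity combination index for fixed-ratio (ray) designs.

For a fixed PD:AZ concentration ratio ``r`` and an effect level ``y``
(% growth inhibition), the combination index is

    CI(E_y) = d_PD / D_PD + d_AZ / D_AZ = r * d_AZ / D_PD + d_AZ / D_AZ

where ``d_PD`` and ``d_AZ`` are the component doses of the combination that
achieve y% inhibition (the combination curve is parameterised on the AZ
component, so ``d_PD = r * d_AZ``) and ``D_PD``, ``D_AZ`` are the
single-agent doses achieving the same effect.  CI = 1 is additivity;
profiles are evaluated on the E50–E80 grid and summarised by their median.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .dose_response import (
    DEFAULT_EXTRAPOLATION_LIMIT,
    DoseStatus,
    FourPLFit,
    dose_at_inhibition,
)
from .errors import DomainError, InvalidInputError

__all__ = [
    "FixedRatioDesign",
    "CIPoint",
    "CIProfile",
    "CICensoring",
    "SynergyClass",
    "ci_at_effect",
    "ci_profile",
    "classify_ci",
    "default_effect_grid",
    "CI_STRONG_SYNERGY",
    "CI_SYNERGY",
    "CI_ANTAGONISM",
]

#: Classification bands on the summary combination index.
CI_STRONG_SYNERGY = 0.5
CI_SYNERGY = 0.8
CI_ANTAGONISM = 1.2


def default_effect_grid() -> np.ndarray:
    """E50…E80 in 1-point steps (31 levels)."""
    return np.arange(50.0, 81.0, 1.0)


@dataclass(frozen=True)
class FixedRatioDesign:
    """Fixed PD:AZ ratio ray; the combination dose axis is the AZ component."""

    r: float

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise DomainError(f"ratio must be positive, got {self.r}")

    @property
    def total_dose_factor(self) -> float:
        """Total combination concentration per unit of AZ-component dose."""
        return 1.0 + self.r


class CICensoring(enum.Enum):
    EXACT = "exact"
    UPPER_BOUND = "upper_bound"
    UNATTAINABLE = "unattainable"


@dataclass(frozen=True)
class CIPoint:
    y: float
    d_pd: float
    d_az: float
    D_pd: float
    D_az: float
    ci: float
    censoring: CICensoring

    @property
    def attainable(self) -> bool:
        return self.censoring is not CICensoring.UNATTAINABLE


@dataclass(frozen=True)
class CIProfile:
    points: tuple[CIPoint, ...]
    grid: tuple[float, ...]
    n_attainable: int
    median: float
    mean: float
    q1: float
    q3: float
    min: float
    max: float
    defined: bool


@dataclass(frozen=True)
class SynergyClass:
    label: str  # strong_synergism | synergism | additive | antagonism
    basis: float  # the summary CI that produced the label


def ci_at_effect(
    fit_pd: FourPLFit,
    fit_az: FourPLFit,
    fit_combo: FourPLFit,
    design: FixedRatioDesign,
    level: float,
    extrapolation_limit: float = DEFAULT_EXTRAPOLATION_LIMIT,
) -> CIPoint:
    """Combination index at one effect level.

    The combination fit must be parameterised on the AZ-component dose axis.
    If any required dose is unattainable the point is flagged unattainable
    (``ci`` is NaN).  If any dose is censored at the extrapolation limit the
    CI is computed with the limit value and flagged ``UPPER_BOUND``: a
    censored single-agent D underestimates the denominator, so the true CI
    cannot exceed the reported value.
    """
    for name, f in (("PD", fit_pd), ("AZ", fit_az), ("combination", fit_combo)):
        if not f.converged:
            raise InvalidInputError(f"{name} fit did not converge; CI undefined")
    d_az_r = dose_at_inhibition(fit_combo, level, extrapolation_limit)
    D_pd_r = dose_at_inhibition(fit_pd, level, extrapolation_limit)
    D_az_r = dose_at_inhibition(fit_az, level, extrapolation_limit)
    if not (d_az_r.attainable and D_pd_r.attainable and D_az_r.attainable):
        return CIPoint(level, math.nan, math.nan, math.nan, math.nan,
                       math.nan, CICensoring.UNATTAINABLE)
    d_az = d_az_r.dose
    d_pd = design.r * d_az
    ci = d_pd / D_pd_r.dose + d_az / D_az_r.dose
    censored = any(r.status is DoseStatus.CENSORED for r in (d_az_r, D_pd_r, D_az_r))
    cens = CICensoring.UPPER_BOUND if censored else CICensoring.EXACT
    return CIPoint(level, float(d_pd), float(d_az), D_pd_r.dose, D_az_r.dose, float(ci), cens)


def ci_profile(
    fit_pd: FourPLFit,
    fit_az: FourPLFit,
    fit_combo: FourPLFit,
    design: FixedRatioDesign,
    grid: np.ndarray | None = None,
    extrapolation_limit: float = DEFAULT_EXTRAPOLATION_LIMIT,
    min_attainable: int = 3,
) -> CIProfile:
    """Evaluate the CI over an effect grid (default E50…E80) and summarise.

    Summary statistics cover attainable points only (exact or upper-bound
    censored).  Profiles with fewer than ``min_attainable`` attainable
    points are flagged undefined (summaries NaN).
    """
    if grid is None:
        grid = default_effect_grid()
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise DomainError("effect grid must be non-empty")
    if np.any((grid <= 0) | (grid >= 100)):
        raise DomainError("effect grid levels must lie in (0, 100)")
    points = tuple(
        ci_at_effect(fit_pd, fit_az, fit_combo, design, float(y), extrapolation_limit)
        for y in grid
    )
    cis = np.array([p.ci for p in points if p.attainable])
    n_att = int(cis.size)
    if n_att >= min_attainable:
        summary = dict(
            median=float(np.median(cis)), mean=float(np.mean(cis)),
            q1=float(np.quantile(cis, 0.25)), q3=float(np.quantile(cis, 0.75)),
            min=float(np.min(cis)), max=float(np.max(cis)), defined=True,
        )
    else:
        summary = dict(median=math.nan, mean=math.nan, q1=math.nan, q3=math.nan,
                       min=math.nan, max=math.nan, defined=False)
    return CIProfile(points=points, grid=tuple(float(y) for y in grid),
                     n_attainable=n_att, **summary)


def classify_ci(summary_ci: float) -> SynergyClass:
    """Band the summary CI: <0.5 strong synergism, <0.8 synergism,
    0.8–1.2 additive (bounds inclusive), >1.2 antagonism."""
    if not summary_ci > 0:
        raise DomainError(f"summary CI must be positive, got {summary_ci}")
    if summary_ci < CI_STRONG_SYNERGY:
        label = "strong_synergism"
    elif summary_ci < CI_SYNERGY:
        label = "synergism"
    elif summary_ci <= CI_ANTAGONISM:
        label = "additive"
    else:
        label = "antagonism"
    return SynergyClass(label=label, basis=float(summary_ci))
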