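"""Four-parameter logistic (4PL) dose-response fitting and inversion.

Viability (% of vehicle control) as a function of dose ``d`` is modelled as

    v(d) = bottom + (top - bottom) / (1 + (d / ic50) ** hill)

with ``hill > 0`` so the curve is non-increasing in dose.  Fitting is
performed on log10(dose) with bounded least squares and a deterministic
multi-start schedule.  Fitted curves are inverted in closed form to the
dose producing a requested growth-inhibition level (IC_y), with explicit
censoring when that dose exceeds an extrapolation limit, and single-agent
potency is classified against fixed micromolar thresholds.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DegenerateDataError, DomainError, InvalidDesignError, InvalidInputError

__all__ = [
    "DoseSeries",
    "FourPLFit",
    "FitBounds",
    "EffectDose",
    "DoseStatus",
    "SensitivityClass",
    "fit_four_pl",
    "predict_viability",
    "dose_at_inhibition",
    "classify_sensitivity",
    "SENSITIVE_UM",
    "RESISTANT_UM",
    "ATTAINABILITY_MARGIN",
    "DEFAULT_EXTRAPOLATION_LIMIT",
]

#: IC50 below this (μM) classifies a line as sensitive.
SENSITIVE_UM = 2.0
#: IC50 above this (μM) classifies a line as resistant.
RESISTANT_UM = 10.0
#: Effect levels within this many percentage points of the maximal
#: inhibition asymptote are treated as unattainable (inverse dose diverges).
ATTAINABILITY_MARGIN = 2.0
#: Default multiple of the maximum tested dose beyond which IC_y is censored.
DEFAULT_EXTRAPOLATION_LIMIT = 10.0

# multi-start ic50 initialisations: quantiles of the log10 dose grid
_START_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)
# relative tolerance for declaring a parameter pinned to its bound
_PIN_RTOL = 1e-4


@dataclass(frozen=True)
class DoseSeries:
    """One condition's dose grid with replicate viability measurements.

    Parameters
    ----------
    condition_id
        Free-text label of the condition (cell line / drug / ratio).
    doses
        Strictly increasing, strictly positive concentrations in μM.
    viability
        Per-dose sequences of replicate viabilities (% of DMSO control).
    """

    condition_id: str
    doses: tuple[float, ...]
    viability: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        via = tuple(tuple(float(v) for v in row) for row in self.viability)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viability", via)
        if len(doses) != len(via):
            raise InvalidDesignError("doses and viability must have equal length")
        if any(d <= 0 for d in doses):
            raise InvalidDesignError("all doses must be strictly positive")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise InvalidDesignError("doses must be strictly increasing")
        if any(len(row) == 0 for row in via):
            raise InvalidDesignError("every dose needs at least one replicate")
        if not all(math.isfinite(v) for row in via for v in row):
            raise InvalidDesignError("viability values must be finite")

    @property
    def n_replicates(self) -> int:
        return max(len(row) for row in self.viability)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (dose, viability) arrays with one row per replicate well."""
        d = np.concatenate([[dose] * len(row) for dose, row in zip(self.doses, self.viability)])
        v = np.concatenate([list(row) for row in self.viability])
        return np.asarray(d, float), np.asarray(v, float)


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the 4PL parameters (μM / % scales)."""

    top: tuple[float, float] = (70.0, 120.0)
    bottom: tuple[float, float] = (0.0, 100.0)
    hill: tuple[float, float] = (0.1, 10.0)
    ic50: tuple[float, float] | None = None  # defaults to [min_dose/100, max_dose*limit]
    extrapolation_limit: float = DEFAULT_EXTRAPOLATION_LIMIT

    def ic50_bounds(self, doses: Sequence[float]) -> tuple[float, float]:
        if self.ic50 is not None:
            return self.ic50
        return (min(doses) / 100.0, max(doses) * self.extrapolation_limit)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters for one condition."""

    top: float
    bottom: float
    ic50: float
    hill: float
    dose_range: tuple[float, float]
    converged: bool
    rss: float

    @property
    def max_inhibition(self) -> float:
        """Largest attainable growth inhibition, 100 − bottom (%)."""
        return 100.0 - self.bottom


class DoseStatus(enum.Enum):
    EXACT = "exact"
    CENSORED = "censored"
    UNATTAINABLE = "unattainable"


@dataclass(frozen=True)
class EffectDose:
    """Dose achieving an inhibition level, with censoring status.

    ``status`` is ``CENSORED`` when the true dose exceeds the extrapolation
    limit (``dose`` then holds the limit, a lower bound on the true dose) and
    ``UNATTAINABLE`` when the level exceeds the curve's maximal inhibition
    (``dose`` is then NaN).
    """

    dose: float
    status: DoseStatus

    @property
    def attainable(self) -> bool:
        return self.status is not DoseStatus.UNATTAINABLE


@dataclass(frozen=True)
class SensitivityClass:
    label: str  # sensitive | intermediate | resistant
    ic50: float
    censored: bool


def _four_pl(dose: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    dose = np.asarray(dose, float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ic50, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio**hill)


def predict_viability(fit: FourPLFit, dose: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the fitted curve; dose 0 returns ``top`` by limit convention."""
    out = _four_pl(np.asarray(dose, float), fit.top, fit.bottom, fit.ic50, fit.hill)
    return float(out) if np.isscalar(dose) or np.ndim(dose) == 0 else out


def fit_four_pl(series: DoseSeries, constraints: FitBounds | None = None) -> FourPLFit:
    """Least-squares 4PL fit of replicate viability data on log10(dose).

    All replicates enter as individual observations.  Five deterministic
    starts (IC50 at dose-grid quantiles, hill = 1) are run and the lowest-RSS
    solution kept; ties go to the earliest start, so the result is fully
    deterministic.  ``converged`` is False when every start fails, when the
    IC50 or hill estimate pins to its bound, or when the asymptotes invert.

    Raises
    ------
    InvalidDesignError
        Fewer than 4 distinct doses.
    DegenerateDataError
        All viability values identical (no signal to fit).
    """
    bounds = constraints or FitBounds()
    if len(set(series.doses)) < 4:
        raise InvalidDesignError(
            f"{series.condition_id}: need >=4 distinct doses, got {len(set(series.doses))}"
        )
    dose, via = series.flat()
    if np.ptp(via) == 0.0:
        raise DegenerateDataError(f"{series.condition_id}: all viability values are constant")

    log_d = np.log10(dose)
    ic50_lo, ic50_hi = bounds.ic50_bounds(series.doses)
    lo = np.array([bounds.top[0], bounds.bottom[0], np.log10(ic50_lo), bounds.hill[0]])
    hi = np.array([bounds.top[1], bounds.bottom[1], np.log10(ic50_hi), bounds.hill[1]])

    def resid(p: np.ndarray) -> np.ndarray:
        top, bottom, log_ic50, hill = p
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_d - log_ic50))) - via

    top0 = float(np.clip(via.max(), *bounds.top))
    bottom0 = float(np.clip(via.min(), *bounds.bottom))
    grid = np.log10(np.asarray(series.doses))
    best = None
    for q in _START_QUANTILES:
        x0 = np.array([top0, bottom0, float(np.quantile(grid, q)), 1.0])
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:  # pragma: no cover - scipy raises only on bad input
            continue
        if not sol.success:
            continue
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol

    d_range = (min(series.doses), max(series.doses))
    if best is None:
        return FourPLFit(top0, bottom0, 10.0 ** float(np.median(grid)), 1.0,
                         d_range, converged=False, rss=float(np.sum(resid(np.array(
                             [top0, bottom0, float(np.median(grid)), 1.0])) ** 2)))

    top, bottom, log_ic50, hill = best.x
    rss = float(2.0 * best.cost)

    def pinned(value: float, lo_v: float, hi_v: float) -> bool:
        span = hi_v - lo_v
        return value - lo_v < _PIN_RTOL * span or hi_v - value < _PIN_RTOL * span

    # only the interior shape parameters flag non-convergence: bottom = 0
    # (complete kill) and top near its bounds are legitimate solutions
    ok = not pinned(log_ic50, lo[2], hi[2]) and not pinned(hill, lo[3], hi[3])
    ok = ok and bottom < top
    return FourPLFit(float(top), float(bottom), float(10.0**log_ic50), float(hill),
                     d_range, converged=bool(ok), rss=rss)


def dose_at_inhibition(
    fit: FourPLFit,
    level: float,
    extrapolation_limit: float = DEFAULT_EXTRAPOLATION_LIMIT,
) -> EffectDose:
    """Invert the fitted curve to the dose giving ``level`` % inhibition.

    Inhibition is measured from 100% viability: the returned dose ``d``
    solves ``100 - v(d) = level`` in closed form.  Levels within
    ``ATTAINABILITY_MARGIN`` of the maximal inhibition (or not reached at
    all because ``top`` < 100) give an unattainable result rather than an
    exception, so callers can censor downstream combination indices.  Doses
    beyond ``extrapolation_limit`` times the maximum tested dose are
    censored at that limit.
    """
    if not fit.converged:
        raise InvalidInputError("dose_at_inhibition requires a converged fit")
    if not 0.0 < level < 100.0:
        raise DomainError(f"effect level must lie in (0, 100), got {level}")
    if level > fit.max_inhibition - ATTAINABILITY_MARGIN:
        return EffectDose(math.nan, DoseStatus.UNATTAINABLE)
    target_viability = 100.0 - level
    if target_viability >= fit.top:
        return EffectDose(math.nan, DoseStatus.UNATTAINABLE)
    ratio = (fit.top - target_viability) / (target_viability - fit.bottom)
    d = fit.ic50 * ratio ** (1.0 / fit.hill)
    limit = extrapolation_limit * fit.dose_range[1]
    if d > limit:
        return EffectDose(limit, DoseStatus.CENSORED)
    return EffectDose(float(d), DoseStatus.EXACT)


def classify_sensitivity(
    ic50: float,
    censored: bool = False,
    sensitive_um: float = SENSITIVE_UM,
    resistant_um: float = RESISTANT_UM,
) -> SensitivityClass:
    """Classify an IC50 against the fixed 2/10 μM thresholds.

    Strict inequalities: IC50 < 2 μM → sensitive, IC50 > 10 μM → resistant,
    anything else (the boundaries included) → intermediate.  A censored IC50
    is a lower bound, so it can never support a "sensitive" call; censored
    values above the resistant threshold are resistant, others intermediate.
    """
    if not ic50 > 0:
        raise DomainError(f"ic50 must be positive, got {ic50}")
    if censored:
        label = "resistant" if ic50 > resistant_um else "intermediate"
    elif ic50 < sensitive_um:
        label = "sensitive"
    elif ic50 > resistant_um:
        label = "resistant"
    else:
        label = "intermediate"
    return SensitivityClass(label=label, ic50=float(ic50), censored=bool(censored))
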