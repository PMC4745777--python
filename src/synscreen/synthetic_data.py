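"""Ground-truth dose-response panel simulator.

Generates single-agent 4PL viability curves spanning realistic IC50 ranges
and fixed-ratio combination curves constructed to carry a chosen *constant*
Loewe interaction index κ, so that every downstream stage (fitting,
inversion, combination-index computation, panel roll-ups) can be validated
against known truth.  Noise is multiplicative lognormal per well.

The constant-index construction inverts the Loewe equation: at effect level
y the AZ-component dose of the combination is

    d_AZ(y) = κ / ( r / D_PD(y) + 1 / D_AZ(y) )

which by substitution gives CI(y) = κ exactly for every y.  The monotone
map dose → effect is recovered by monotone interpolation of (d_AZ(y), y)
over a dense effect grid.  κ is a simplification: real combinations may
have effect-level-dependent interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import DoseSeries
from .errors import DomainError, UnusableDesignError
from .loewe_combination import FixedRatioDesign

__all__ = [
    "TrueCurve",
    "SyntheticPanelSpec",
    "GroundTruth",
    "default_single_agent_grid",
    "default_combo_grid",
    "single_agent_inverse",
    "combo_az_dose_at_effect",
    "combination_viability",
    "simulate_single_agent",
    "simulate_combination",
    "simulate_panel",
    "format_ratio",
]


def default_single_agent_grid() -> tuple[float, ...]:
    """9-point half-log grid, 0.01–100 μM."""
    return tuple(float(10.0 ** (e / 2.0)) for e in range(-4, 5))


def default_combo_grid() -> tuple[float, ...]:
    """9-point half-log grid on the AZ axis, 0.004–40 μM."""
    return tuple(float(0.004 * 10.0 ** (e / 2.0)) for e in range(0, 9))


def format_ratio(r: float) -> str:
    """Render a PD:AZ ratio as the conventional ``0.25:1`` string."""
    return f"{r:g}:1"


@dataclass(frozen=True)
class TrueCurve:
    """Generating 4PL parameters (top fixed near 100 by normalisation)."""

    top: float
    bottom: float
    ic50: float
    hill: float

    def viability(self, dose: np.ndarray | float) -> np.ndarray | float:
        dose = np.asarray(dose, float)
        out = self.bottom + (self.top - self.bottom) / (1.0 + (dose / self.ic50) ** self.hill)
        return out

    @property
    def max_inhibition(self) -> float:
        return 100.0 - self.bottom


def single_agent_inverse(curve: TrueCurve, y: np.ndarray | float) -> np.ndarray | float:
    """Closed-form dose giving y% inhibition on a true curve (no censoring)."""
    y = np.asarray(y, float)
    v = 100.0 - y
    if np.any(v >= curve.top) or np.any(v <= curve.bottom):
        raise DomainError("effect level outside the curve's attainable range")
    ratio = (curve.top - v) / (v - curve.bottom)
    return curve.ic50 * ratio ** (1.0 / curve.hill)


def combo_az_dose_at_effect(
    truth_pd: TrueCurve, truth_az: TrueCurve, design: FixedRatioDesign,
    kappa: float, y: np.ndarray | float,
) -> np.ndarray | float:
    """AZ-component dose at which the constant-κ combination reaches y%."""
    D_pd = single_agent_inverse(truth_pd, y)
    D_az = single_agent_inverse(truth_az, y)
    return kappa / (design.r / D_pd + 1.0 / D_az)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal factors with coefficient of variation cv."""
    if cv < 0:
        raise DomainError(f"noise_cv must be non-negative, got {cv}")
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_single_agent(
    truth: TrueCurve,
    dose_grid,
    noise_cv: float,
    n_replicates: int,
    rng: np.random.Generator | int,
    condition_id: str = "single",
) -> DoseSeries:
    """Sample replicate viabilities from a true curve with lognormal noise."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    doses = np.asarray(dose_grid, float)
    clean = np.asarray(truth.viability(doses), float)
    noise = _lognormal_noise(rng, noise_cv, (doses.size, n_replicates))
    values = clean[:, None] * noise
    return DoseSeries(condition_id, tuple(doses), tuple(tuple(row) for row in values))


def combination_viability(
    truth_pd: TrueCurve, truth_az: TrueCurve, design: FixedRatioDesign,
    kappa: float, az_doses: np.ndarray, n_effect: int = 4000,
) -> np.ndarray:
    """Noise-free combination viability on the AZ-component dose axis.

    Built by tabulating d_AZ(y) on a dense effect grid and inverting the
    monotone map with log-dose interpolation; doses outside the tabulated
    range clamp to the nearest attainable effect.
    """
    if not kappa > 0:
        raise DomainError(f"kappa must be positive, got {kappa}")
    y_hi = min(truth_pd.max_inhibition, truth_az.max_inhibition) - 0.05
    y_lo = max(100.0 - min(truth_pd.top, truth_az.top) + 0.05, 0.05)
    if y_hi <= y_lo:
        raise UnusableDesignError("true curves have no common attainable effect range")
    y_dense = np.linspace(y_lo, y_hi, n_effect)
    d_dense = np.asarray(
        combo_az_dose_at_effect(truth_pd, truth_az, design, kappa, y_dense), float
    )
    az_doses = np.asarray(az_doses, float)
    if d_dense[0] > az_doses[-1] or d_dense[-1] < az_doses[0]:
        raise UnusableDesignError(
            "combination curve lies entirely outside the dose grid; "
            "adjust kappa or widen the grid"
        )
    y_at_dose = np.interp(np.log10(az_doses), np.log10(d_dense), y_dense,
                          left=y_lo, right=y_hi)
    return 100.0 - y_at_dose


def simulate_combination(
    truth_pd: TrueCurve,
    truth_az: TrueCurve,
    design: FixedRatioDesign,
    kappa: float,
    dose_grid,
    noise_cv: float,
    n_replicates: int,
    rng: np.random.Generator | int,
    condition_id: str = "combo",
) -> DoseSeries:
    """Sample a fixed-ratio combination series with constant Loewe index κ.

    The series is parameterised on the AZ-component dose axis; the PD
    component at each point is ``r`` times the listed dose.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    doses = np.asarray(dose_grid, float)
    clean = combination_viability(truth_pd, truth_az, design, kappa, doses)
    noise = _lognormal_noise(rng, noise_cv, (doses.size, n_replicates))
    values = clean[:, None] * noise
    return DoseSeries(condition_id, tuple(doses), tuple(tuple(row) for row in values))


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Configuration for a full synthetic cell-line panel.

    IC50s are drawn log10-uniformly per drug; κ values are assigned per line
    and ratio.  ``kappa_values`` may be a single float (shared), a sequence
    of per-line values recycled across ratios, or a mapping ratio → per-line
    sequence.
    """

    n_lines: int = 28
    pd_ic50_log10_range: tuple[float, float] = (-1.5, 2.0)   # ~0.03–100 μM
    az_ic50_log10_range: tuple[float, float] = (-0.85, 1.55)  # ~0.14–35 μM
    hill_range: tuple[float, float] = (0.8, 1.5)
    bottom_range: tuple[float, float] = (0.0, 5.0)
    top: float = 100.0
    single_agent_grid: tuple[float, ...] = field(default_factory=default_single_agent_grid)
    combo_grid: tuple[float, ...] = field(default_factory=default_combo_grid)
    ratio_set: tuple[float, ...] = (4.0, 1.0, 0.25)
    kappa_values: object = 1.0
    noise_cv: float = 0.05
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pd_ic50_log10_range", "az_ic50_log10_range", "hill_range", "bottom_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise DomainError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be non-negative")
        if self.n_lines < 1 or self.n_replicates < 1:
            raise DomainError("n_lines and n_replicates must be >= 1")
        grid = self.single_agent_grid
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise DomainError("single_agent_grid must be strictly increasing")

    def kappa_for(self, line_index: int, ratio: float) -> float:
        k = self.kappa_values
        if isinstance(k, dict):
            k = k[ratio]
        if np.ndim(k) == 0:
            return float(k)
        return float(np.asarray(k, float)[line_index % len(np.asarray(k))])


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters emitted alongside simulated data."""

    table: pd.DataFrame  # one row per line: true curve params + κ per ratio


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent per-line/per-condition stream; stable under panel growth."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def simulate_panel(spec: SyntheticPanelSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full panel as a long-format table plus its ground truth.

    Returns a DataFrame with columns ``cell_line, condition, ratio, dose_uM,
    replicate, viability_pct`` (the format consumed by the screening
    pipeline) and a :class:`GroundTruth` carrying the generating parameters.
    Deterministic for a fixed spec (per-line, per-condition RNG streams).
    """
    rows: list[tuple] = []
    truth_rows: list[dict] = []
    for i in range(spec.n_lines):
        name = f"SYN{i + 1:03d}"
        prng = _stream(spec.seed, i, 0)
        pd_curve = TrueCurve(
            top=spec.top,
            bottom=float(prng.uniform(*spec.bottom_range)),
            ic50=float(10.0 ** prng.uniform(*spec.pd_ic50_log10_range)),
            hill=float(prng.uniform(*spec.hill_range)),
        )
        az_curve = TrueCurve(
            top=spec.top,
            bottom=float(prng.uniform(*spec.bottom_range)),
            ic50=float(10.0 ** prng.uniform(*spec.az_ic50_log10_range)),
            hill=float(prng.uniform(*spec.hill_range)),
        )
        truth = {
            "cell_line": name,
            "pd_top": pd_curve.top, "pd_bottom": pd_curve.bottom,
            "pd_ic50_uM": pd_curve.ic50, "pd_hill": pd_curve.hill,
            "az_top": az_curve.top, "az_bottom": az_curve.bottom,
            "az_ic50_uM": az_curve.ic50, "az_hill": az_curve.hill,
        }
        series = {
            ("PD", ""): simulate_single_agent(
                pd_curve, spec.single_agent_grid, spec.noise_cv, spec.n_replicates,
                _stream(spec.seed, i, 1), condition_id=f"{name}|PD"),
            ("AZ", ""): simulate_single_agent(
                az_curve, spec.single_agent_grid, spec.noise_cv, spec.n_replicates,
                _stream(spec.seed, i, 2), condition_id=f"{name}|AZ"),
        }
        for j, r in enumerate(spec.ratio_set):
            kappa = spec.kappa_for(i, r)
            truth[f"kappa_{format_ratio(r)}"] = kappa
            series[("COMBO", format_ratio(r))] = simulate_combination(
                pd_curve, az_curve, FixedRatioDesign(r), kappa, spec.combo_grid,
                spec.noise_cv, spec.n_replicates, _stream(spec.seed, i, 3 + j),
                condition_id=f"{name}|COMBO|{format_ratio(r)}")
        truth_rows.append(truth)
        for (cond, ratio), s in series.items():
            for dose, reps in zip(s.doses, s.viability):
                for k, v in enumerate(reps, start=1):
                    rows.append((name, cond, ratio, dose, k, v))
    data = pd.DataFrame(
        rows, columns=["cell_line", "condition", "ratio", "dose_uM", "replicate",
                       "viability_pct"],
    )
    return data, GroundTruth(table=pd.DataFrame(truth_rows))
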