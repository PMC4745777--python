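"""Panel-level screening: fit every condition, classify, score, roll up.

Consumes long-format dose-response tables (cell_line, condition, ratio,
dose_uM, replicate, viability_pct), fits 4PL curves per condition, computes
single-agent and combination sensitivity classes, per-ratio Loewe CI
profiles and synergy classes, and aggregates panel counts with integer
percentages.  The pipeline is deterministic: inputs are sorted internally
so row order never affects output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import dose_response as dr
from . import loewe_combination as lw
from .dose_response import DoseSeries, DoseStatus, FourPLFit, SensitivityClass
from .errors import DomainError, SynscreenError, UndefinedResultError
from .loewe_combination import CIProfile, FixedRatioDesign, SynergyClass
from .synthetic_data import format_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "CellLineRecord",
    "PanelResult",
    "read_dose_table",
    "series_from_table",
    "screen_panel",
    "screen_table",
    "sensitivity_summary",
    "select_optimal_ratio",
    "round_half_up_pct",
    "fits_table",
    "ci_points_table",
    "ci_summary_table",
]

SINGLE_AGENTS = ("PD", "AZ")


@dataclass(frozen=True)
class ScreenConfig:
    """Versioned analysis configuration (thresholds, grid, censoring, seed)."""

    sensitive_uM: float = dr.SENSITIVE_UM
    resistant_uM: float = dr.RESISTANT_UM
    ci_bands: tuple[float, float, float] = (lw.CI_STRONG_SYNERGY, lw.CI_SYNERGY,
                                            lw.CI_ANTAGONISM)
    effect_grid: tuple[float, ...] = tuple(float(y) for y in range(50, 81))
    extrapolation_limit: float = dr.DEFAULT_EXTRAPOLATION_LIMIT
    seed: int = 0
    version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for k in ("ci_bands", "effect_grid"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        payload = {
            "version": self.version,
            "sensitive_uM": self.sensitive_uM,
            "resistant_uM": self.resistant_uM,
            "ci_bands": list(self.ci_bands),
            "effect_grid": [float(y) for y in self.effect_grid],
            "extrapolation_limit": self.extrapolation_limit,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class CellLineRecord:
    name: str
    fits: dict = field(default_factory=dict)          # condition key -> FourPLFit
    sensitivity: dict = field(default_factory=dict)   # condition key -> SensitivityClass
    ci_profiles: dict = field(default_factory=dict)   # ratio -> CIProfile
    synergy: dict = field(default_factory=dict)       # ratio -> SynergyClass


@dataclass
class PanelResult:
    lines: list
    ratio_set: list
    counts: dict           # condition key -> {sensitive, intermediate, resistant}
    synergy_counts: dict   # ratio -> {strong_synergism, synergism, additive, antagonism}
    optimal_ratio: float | None
    exclusions: pd.DataFrame
    n_lines: int


def round_half_up_pct(count: int, total: int) -> int:
    """Integer percentage with half-up rounding (8/28 → 29)."""
    if total <= 0:
        raise DomainError("total must be positive")
    return int(math.floor(100.0 * count / total + 0.5))


def _parse_ratio(text: str) -> float:
    """Parse a ``'0.25:1'`` style ratio string to the PD:AZ quotient."""
    s = str(text).strip()
    if ":" in s:
        num, den = s.split(":")
        return float(num) / float(den)
    return float(s)


def read_dose_table(path) -> pd.DataFrame:
    """Load and validate a long-format dose-response CSV."""
    df = pd.read_csv(path, dtype={"ratio": str}, keep_default_na=False,
                     float_precision="round_trip")
    required = {"cell_line", "condition", "ratio", "dose_uM", "replicate", "viability_pct"}
    missing = required - set(df.columns)
    if missing:
        raise SynscreenError(f"dose table missing columns: {sorted(missing)}")
    return df


def series_from_table(df: pd.DataFrame) -> dict:
    """Group a long table into DoseSeries keyed by (line, condition, ratio).

    The ratio key is the PD:AZ quotient as a float for COMBO rows and ``None``
    for single agents.  Rows are sorted internally so the grouping is
    independent of input row order.
    """
    df = df.copy()
    df["ratio"] = df["ratio"].fillna("").astype(str)
    df = df.sort_values(["cell_line", "condition", "ratio", "dose_uM", "replicate"],
                        kind="mergesort")
    out: dict = {}
    for (line, cond, ratio_s), grp in df.groupby(["cell_line", "condition", "ratio"],
                                                 sort=True):
        ratio = _parse_ratio(ratio_s) if cond == "COMBO" and ratio_s.strip() else None
        doses, reps = [], []
        for dose, dg in grp.groupby("dose_uM", sort=True):
            doses.append(float(dose))
            reps.append(tuple(dg["viability_pct"].astype(float)))
        label = f"{line}|{cond}" + (f"|{ratio_s}" if ratio is not None else "")
        out[(line, cond, ratio)] = DoseSeries(label, tuple(doses), tuple(reps))
    return out


def _combo_total_ic50(fit_combo: FourPLFit, design: FixedRatioDesign,
                      limit: float) -> tuple[float, bool] | None:
    """Combination IC50 reported as *total* drug concentration (PD + AZ).

    The combination fit is parameterised on the AZ-component axis, so total
    dose is (1 + r) times the AZ-axis IC50.  Returns None when 50%
    inhibition is unattainable.
    """
    res = dr.dose_at_inhibition(fit_combo, 50.0, limit)
    if not res.attainable:
        return None
    return design.total_dose_factor * res.dose, res.status is DoseStatus.CENSORED


def screen_panel(data: dict, config: ScreenConfig | None = None) -> PanelResult:
    """Run the full deterministic screen over DoseSeries keyed by
    (line, condition, ratio).

    Every line must carry PD and AZ single-agent series before its
    combinations are analysed; structural problems (missing single agents,
    failed fits, undefined CI profiles) are collected in an exclusions table
    rather than silently dropped.
    """
    config = config or ScreenConfig()
    grid = np.asarray(config.effect_grid, float)
    lines = sorted({k[0] for k in data})
    ratio_set = sorted({k[2] for k in data if k[2] is not None})
    records: list[CellLineRecord] = []
    exclusions: list[dict] = []

    def exclude(line: str, cond: str, reason: str) -> None:
        logger.info("excluding %s/%s: %s", line, cond, reason)
        exclusions.append({"cell_line": line, "condition": cond, "reason": reason})

    for line in lines:
        rec = CellLineRecord(name=line)
        has_combo = any(k[0] == line and k[1] == "COMBO" for k in data)
        missing_sa = [c for c in SINGLE_AGENTS if (line, c, None) not in data]
        if missing_sa and has_combo:
            exclude(line, "+".join(missing_sa),
                    "combination present but single-agent series missing")
        for cond in SINGLE_AGENTS:
            key = (line, cond, None)
            if key not in data:
                continue
            try:
                fit = dr.fit_four_pl(data[key])
            except SynscreenError as exc:
                exclude(line, cond, f"fit failed: {exc}")
                continue
            rec.fits[cond] = fit
            if not fit.converged:
                exclude(line, cond, "fit did not converge")
                continue
            ic50 = dr.dose_at_inhibition(fit, 50.0, config.extrapolation_limit)
            if not ic50.attainable:
                exclude(line, cond, "50% inhibition unattainable")
                continue
            rec.sensitivity[cond] = dr.classify_sensitivity(
                ic50.dose, ic50.status is DoseStatus.CENSORED,
                config.sensitive_uM, config.resistant_uM)
        for ratio in ratio_set:
            key = (line, "COMBO", ratio)
            if key not in data:
                continue
            cond_name = f"COMBO:{format_ratio(ratio)}"
            if not all(c in rec.fits and rec.fits[c].converged for c in SINGLE_AGENTS):
                exclude(line, cond_name, "usable single-agent fits unavailable")
                continue
            try:
                fit_c = dr.fit_four_pl(data[key])
            except SynscreenError as exc:
                exclude(line, cond_name, f"fit failed: {exc}")
                continue
            rec.fits[cond_name] = fit_c
            if not fit_c.converged:
                exclude(line, cond_name, "fit did not converge")
                continue
            design = FixedRatioDesign(ratio)
            total = _combo_total_ic50(fit_c, design, config.extrapolation_limit)
            if total is not None:
                rec.sensitivity[cond_name] = dr.classify_sensitivity(
                    total[0], total[1], config.sensitive_uM, config.resistant_uM)
            profile = lw.ci_profile(rec.fits["PD"], rec.fits["AZ"], fit_c, design,
                                    grid, config.extrapolation_limit)
            rec.ci_profiles[ratio] = profile
            if profile.defined:
                rec.synergy[ratio] = lw.classify_ci(profile.median)
            else:
                exclude(line, cond_name,
                        f"CI profile undefined ({profile.n_attainable} attainable points)")
        records.append(rec)

    counts: dict = {}
    cond_keys = sorted({c for r in records for c in r.sensitivity})
    for cond in cond_keys:
        tally = {"sensitive": 0, "intermediate": 0, "resistant": 0}
        for rec in records:
            cls = rec.sensitivity.get(cond)
            if cls is not None:
                tally[cls.label] += 1
        counts[cond] = tally
    synergy_counts: dict = {}
    for ratio in ratio_set:
        tally = {"strong_synergism": 0, "synergism": 0, "additive": 0, "antagonism": 0}
        for rec in records:
            cls = rec.synergy.get(ratio)
            if cls is not None:
                tally[cls.label] += 1
        synergy_counts[ratio] = tally

    result = PanelResult(
        lines=records, ratio_set=ratio_set, counts=counts,
        synergy_counts=synergy_counts, optimal_ratio=None,
        exclusions=pd.DataFrame(exclusions,
                                columns=["cell_line", "condition", "reason"]),
        n_lines=len(records),
    )
    try:
        result.optimal_ratio = select_optimal_ratio(result)
    except UndefinedResultError:
        result.optimal_ratio = None
    return result


def screen_table(df: pd.DataFrame, config: ScreenConfig | None = None) -> PanelResult:
    """Convenience wrapper: long-format table in, PanelResult out."""
    return screen_panel(series_from_table(df), config)


def sensitivity_summary(panel: PanelResult, condition: str) -> dict:
    """Counts and half-up integer percentages for one condition."""
    if condition not in panel.counts:
        raise DomainError(f"unknown condition {condition!r}; "
                          f"have {sorted(panel.counts)}")
    tally = panel.counts[condition]
    n = panel.n_lines
    return {
        "condition": condition,
        "n_lines": n,
        **{f"n_{k}": v for k, v in tally.items()},
        **{f"pct_{k}": round_half_up_pct(v, n) for k, v in tally.items()},
    }


def select_optimal_ratio(panel: PanelResult) -> float:
    """Ratio with the most synergistic-or-stronger lines.

    Ties break first by the lower median of per-line median CIs, then by the
    smaller ratio value.
    """
    candidates = []
    for ratio in panel.ratio_set:
        medians = [rec.ci_profiles[ratio].median for rec in panel.lines
                   if ratio in rec.ci_profiles and rec.ci_profiles[ratio].defined]
        if not medians:
            continue
        n_syn = sum(1 for rec in panel.lines
                    if rec.synergy.get(ratio) is not None
                    and rec.synergy[ratio].label in ("synergism", "strong_synergism"))
        candidates.append((-n_syn, float(np.median(medians)), ratio))
    if not candidates:
        raise UndefinedResultError("no ratio has a valid CI summary")
    return min(candidates)[2]


# ---------------------------------------------------------------------------
# tabular output

def fits_table(panel: PanelResult) -> pd.DataFrame:
    """Per-condition fit parameters and sensitivity calls, one row each."""
    rows = []
    for rec in panel.lines:
        for cond in sorted(rec.fits):
            fit = rec.fits[cond]
            cls = rec.sensitivity.get(cond)
            rows.append({
                "cell_line": rec.name, "condition": cond,
                "top": fit.top, "bottom": fit.bottom, "ic50_uM": fit.ic50,
                "hill": fit.hill, "converged": fit.converged, "rss": fit.rss,
                "ic50_reported_uM": cls.ic50 if cls else np.nan,
                "censored": cls.censored if cls else False,
                "ic50_class": cls.label if cls else "",
            })
    return pd.DataFrame(rows)


def ci_points_table(panel: PanelResult) -> pd.DataFrame:
    """Per-line, per-ratio CI profile points (all censoring states kept)."""
    rows = []
    for rec in panel.lines:
        for ratio in sorted(rec.ci_profiles):
            for p in rec.ci_profiles[ratio].points:
                rows.append({
                    "cell_line": rec.name, "ratio": format_ratio(ratio), "y": p.y,
                    "d_PD": p.d_pd, "d_AZ": p.d_az, "D_PD": p.D_pd, "D_AZ": p.D_az,
                    "ci": p.ci, "censoring": p.censoring.value,
                })
    return pd.DataFrame(rows)


def ci_summary_table(panel: PanelResult) -> pd.DataFrame:
    """Per-line, per-ratio CI summaries and synergy classes."""
    rows = []
    for rec in panel.lines:
        for ratio in sorted(rec.ci_profiles):
            prof = rec.ci_profiles[ratio]
            syn = rec.synergy.get(ratio)
            rows.append({
                "cell_line": rec.name, "ratio": format_ratio(ratio),
                "median_ci": prof.median, "mean_ci": prof.mean,
                "q1": prof.q1, "q3": prof.q3,
                "n_attainable": prof.n_attainable,
                "synergy_class": syn.label if syn else "",
            })
    return pd.DataFrame(rows)
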