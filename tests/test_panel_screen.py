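import math

import numpy as np
import pandas as pd
import pytest

from synscreen.errors import DomainError, UndefinedResultError
from synscreen.loewe_combination import CIProfile, SynergyClass
from synscreen.panel_screen import (
    CellLineRecord,
    PanelResult,
    ScreenConfig,
    ci_summary_table,
    fits_table,
    read_dose_table,
    round_half_up_pct,
    screen_table,
    select_optimal_ratio,
    sensitivity_summary,
    series_from_table,
)
from synscreen.synthetic_data import SyntheticPanelSpec, simulate_panel


def sham_panel_spec(ic50s, **kw):
    """Panel of sham-like lines: PD and AZ share each line's IC50 range so the
    0.25:1 combination total-dose IC50 is controlled by kappa * ic50."""
    lo = [math.log10(x) for x in ic50s]
    return SyntheticPanelSpec(
        n_lines=len(ic50s),
        pd_ic50_log10_range=(min(lo), max(lo)),
        az_ic50_log10_range=(min(lo), max(lo)),
        **kw,
    )


@pytest.fixture(scope="module")
def small_panel():
    spec = SyntheticPanelSpec(n_lines=6, ratio_set=(0.25, 1.0),
                              kappa_values={0.25: 0.5, 1.0: 1.0},
                              noise_cv=0.02, seed=21)
    data, truth = simulate_panel(spec)
    return data, truth, screen_table(data)


class TestRoundHalfUpPct:
    @pytest.mark.parametrize("count,total,expected", [
        (8, 28, 29), (19, 28, 68), (15, 28, 54), (9, 28, 32),
        (11, 28, 39), (26, 28, 93), (17, 28, 61), (1, 28, 4),
        (0, 28, 0), (28, 28, 100), (1, 8, 13),
    ])
    def test_values(self, count, total, expected):
        assert round_half_up_pct(count, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            round_half_up_pct(1, 0)


class TestSeriesFromTable:
    def test_row_order_invariant(self, small_panel):
        data, _, _ = small_panel
        shuffled = data.sample(frac=1.0, random_state=3)
        a = series_from_table(data)
        b = series_from_table(shuffled)
        assert a == b

    def test_keys_and_ratio_parsing(self, small_panel):
        data, _, _ = small_panel
        keys = series_from_table(data).keys()
        lines = set(data["cell_line"])
        for line in lines:
            assert (line, "PD", None) in keys
            assert (line, "AZ", None) in keys
            assert (line, "COMBO", 0.25) in keys
            assert (line, "COMBO", 1.0) in keys


class TestScreenPanel:
    def test_ground_truth_synergy_recovery(self, small_panel):
        _, truth, panel = small_panel
        # kappa 0.5 at 0.25:1 sits on the synergism band edge; use 1:1 additive
        assert panel.synergy_counts[1.0]["additive"] == 6
        for rec in panel.lines:
            assert rec.ci_profiles[0.25].median == pytest.approx(0.5, abs=0.05)

    def test_counts_conserve_panel_size(self, small_panel):
        _, _, panel = small_panel
        for cond, tally in panel.counts.items():
            assert sum(tally.values()) == panel.n_lines

    def test_single_agent_sensitivity_matches_truth(self, small_panel):
        _, truth, panel = small_panel
        by_name = {rec.name: rec for rec in panel.lines}
        for _, row in truth.table.iterrows():
            for cond, col in (("PD", "pd_ic50_uM"), ("AZ", "az_ic50_uM")):
                true_ic50 = row[col]
                if 1.8 < true_ic50 < 2.2 or 9 < true_ic50 < 11:
                    continue  # skip boundary-adjacent truths under noise
                label = by_name[row["cell_line"]].sensitivity[cond].label
                if true_ic50 < 2:
                    assert label == "sensitive"
                elif true_ic50 > 10:
                    assert label == "resistant"
                else:
                    assert label == "intermediate"

    def test_sham_panel_all_additive(self):
        spec = sham_panel_spec([0.5, 1.0, 3.0], ratio_set=(0.25,),
                               kappa_values=1.0, noise_cv=0.0,
                               hill_range=(1.0, 1.0), bottom_range=(0.0, 0.0),
                               seed=4)
        data, _, = simulate_panel(spec)[0], None
        panel = screen_table(data)
        assert panel.synergy_counts[0.25]["additive"] == 3

    def test_combo_sensitive_count_19_of_28(self):
        # constructed ground truth: 19 lines with combo total-dose IC50 < 2 uM
        ic50 = [0.4] * 19 + [5.0] * 9  # kappa=1 sham-ish: total IC50 ~ ic50
        spec = SyntheticPanelSpec(
            n_lines=28, pd_ic50_log10_range=(0, 0), az_ic50_log10_range=(0, 0),
            ratio_set=(0.25,), kappa_values=1.0, noise_cv=0.01,
            hill_range=(1.0, 1.0), bottom_range=(0.0, 0.0), seed=8)
        # override sampled ic50s by generating per-line panels
        frames = []
        for i, x in enumerate(ic50):
            s = SyntheticPanelSpec(
                n_lines=1, pd_ic50_log10_range=(math.log10(x),) * 2,
                az_ic50_log10_range=(math.log10(x),) * 2, ratio_set=(0.25,),
                kappa_values=1.0, noise_cv=0.01, hill_range=(1.0, 1.0),
                bottom_range=(0.0, 0.0), seed=100 + i)
            df = simulate_panel(s)[0]
            df["cell_line"] = f"L{i:02d}"
            frames.append(df)
        panel = screen_table(pd.concat(frames, ignore_index=True))
        summary = sensitivity_summary(panel, "COMBO:0.25:1")
        assert summary["n_sensitive"] == 19
        assert summary["pct_sensitive"] == 68

    def test_pd_sensitive_count_8_of_28(self):
        ic50s = [0.5] * 8 + [5.0] * 20
        frames = []
        for i, x in enumerate(ic50s):
            s = SyntheticPanelSpec(
                n_lines=1, pd_ic50_log10_range=(math.log10(x),) * 2,
                az_ic50_log10_range=(0.6, 0.6), ratio_set=(), noise_cv=0.01,
                hill_range=(1.0, 1.0), bottom_range=(0.0, 0.0), seed=200 + i)
            df = simulate_panel(s)[0]
            df["cell_line"] = f"L{i:02d}"
            frames.append(df)
        panel = screen_table(pd.concat(frames, ignore_index=True))
        summary = sensitivity_summary(panel, "PD")
        assert summary["n_sensitive"] == 8
        assert summary["pct_sensitive"] == 29

    def test_missing_single_agent_logged(self, small_panel):
        data, _, _ = small_panel
        line = data["cell_line"].iloc[0]
        broken = data[~((data["cell_line"] == line) & (data["condition"] == "PD"))]
        panel = screen_table(broken)
        excl = panel.exclusions
        assert ((excl["cell_line"] == line)).any()
        # line is reported, not silently dropped
        assert line in [rec.name for rec in panel.lines]

    def test_determinism_byte_identical(self, small_panel, tmp_path):
        data, _, _ = small_panel
        outs = []
        for i, frame in enumerate((data, data.sample(frac=1.0, random_state=7))):
            panel = screen_table(frame)
            f = tmp_path / f"fits{i}.csv"
            c = tmp_path / f"ci{i}.csv"
            fits_table(panel).to_csv(f, index=False)
            ci_summary_table(panel).to_csv(c, index=False)
            outs.append((f.read_bytes(), c.read_bytes()))
        assert outs[0] == outs[1]


class TestSensitivitySummary:
    def test_unknown_condition(self, small_panel):
        _, _, panel = small_panel
        with pytest.raises(DomainError):
            sensitivity_summary(panel, "XX")

    def test_percentages_sum_close_to_100(self, small_panel):
        _, _, panel = small_panel
        s = sensitivity_summary(panel, "PD")
        assert s["n_sensitive"] + s["n_intermediate"] + s["n_resistant"] == 6


def _panel_with(synergy_by_ratio, medians_by_ratio):
    """Hand-built PanelResult for select_optimal_ratio unit tests."""
    ratios = sorted(synergy_by_ratio)
    n = len(next(iter(synergy_by_ratio.values())))
    lines = []
    for i in range(n):
        rec = CellLineRecord(name=f"L{i}")
        for r in ratios:
            label = synergy_by_ratio[r][i]
            med = medians_by_ratio[r][i]
            if label is None:
                rec.ci_profiles[r] = CIProfile((), (), 0, math.nan, math.nan,
                                               math.nan, math.nan, math.nan,
                                               math.nan, defined=False)
                continue
            rec.ci_profiles[r] = CIProfile((), (), 31, med, med, med, med,
                                           med, med, defined=True)
            rec.synergy[r] = SynergyClass(label=label, basis=med)
        lines.append(rec)
    return PanelResult(lines=lines, ratio_set=ratios, counts={},
                       synergy_counts={}, optimal_ratio=None,
                       exclusions=pd.DataFrame(), n_lines=n)


class TestSelectOptimalRatio:
    def test_generator_ground_truth(self):
        spec = sham_panel_spec([0.5, 1.5, 4.0], ratio_set=(4.0, 1.0, 0.25),
                               kappa_values={0.25: 0.5, 1.0: 0.9, 4.0: 0.9},
                               noise_cv=0.0, hill_range=(1.0, 1.0),
                               bottom_range=(0.0, 0.0), seed=13)
        panel = screen_table(simulate_panel(spec)[0])
        assert select_optimal_ratio(panel) == 0.25
        assert panel.optimal_ratio == 0.25

    def test_count_dominates(self):
        panel = _panel_with(
            {0.25: ["synergism", "additive"], 1.0: ["synergism", "synergism"]},
            {0.25: [0.6, 1.0], 1.0: [0.75, 0.75]})
        assert select_optimal_ratio(panel) == 1.0

    def test_median_tiebreak(self):
        panel = _panel_with(
            {0.25: ["synergism"], 1.0: ["synergism"]},
            {0.25: [0.7], 1.0: [0.6]})
        assert select_optimal_ratio(panel) == 1.0

    def test_smaller_ratio_tiebreak(self):
        panel = _panel_with(
            {0.25: ["additive"], 1.0: ["additive"], 4.0: ["additive"]},
            {0.25: [1.0], 1.0: [1.0], 4.0: [1.0]})
        assert select_optimal_ratio(panel) == 0.25

    def test_only_valid_ratio_wins(self):
        panel = _panel_with(
            {0.25: [None], 1.0: ["additive"], 4.0: [None]},
            {0.25: [math.nan], 1.0: [1.0], 4.0: [math.nan]})
        assert select_optimal_ratio(panel) == 1.0

    def test_no_valid_summaries(self):
        panel = _panel_with({0.25: [None]}, {0.25: [math.nan]})
        with pytest.raises(UndefinedResultError):
            select_optimal_ratio(panel)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ScreenConfig(sensitive_uM=1.5, seed=77)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        loaded = ScreenConfig.from_yaml(path)
        assert loaded == cfg

    def test_defaults(self):
        cfg = ScreenConfig()
        assert cfg.sensitive_uM == 2.0
        assert cfg.resistant_uM == 10.0
        assert cfg.ci_bands == (0.5, 0.8, 1.2)
        assert cfg.effect_grid[0] == 50.0 and cfg.effect_grid[-1] == 80.0


class TestTables:
    def test_fits_table_columns(self, small_panel):
        _, _, panel = small_panel
        df = fits_table(panel)
        assert {"cell_line", "condition", "top", "bottom", "ic50_uM", "hill",
                "converged", "rss", "censored", "ic50_class"} <= set(df.columns)
        assert len(df) == 6 * 4  # PD, AZ, two combos per line

    def test_read_dose_table_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"cell_line": ["a"], "dose_uM": [1.0]}).to_csv(path, index=False)
        from synscreen.errors import SynscreenError
        with pytest.raises(SynscreenError):
            read_dose_table(path)

    def test_read_dose_table_round_trip(self, small_panel, tmp_path):
        data, _, _ = small_panel
        path = tmp_path / "panel.csv"
        data.to_csv(path, index=False)
        loaded = read_dose_table(path)
        assert series_from_table(loaded) == series_from_table(data)
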