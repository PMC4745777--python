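# synscreen

Fixed-ratio drug-combination synergy screening for cell-viability panels:

- **dose_response** — four-parameter logistic (4PL) fitting of viability
  (% of DMSO control) on log10 dose, closed-form inversion to effect-level
  doses (IC_y) with extrapolation censoring, and sensitivity classification
  (IC50 < 2 μM sensitive, > 10 μM resistant).
- **loewe_combination** — Loewe-additivity combination index
  `CI(E_y) = d_PD/D_PD + d_AZ/D_AZ` for fixed PD:AZ ratio rays, evaluated on
  the E50–E80 effect grid with explicit censoring propagation, summarised by
  the median and classified (CI < 0.5 strong synergism, < 0.8 synergism,
  0.8–1.2 additive, > 1.2 antagonism).
- **panel_screen** — deterministic panel orchestration: fit every condition,
  classify sensitivity and synergy per ratio, pick the optimal ratio, emit
  roll-up tables and an exclusions log.
- **downstream_metrics** — scalar assay formulas: wound closure %, relative
  to control ratios, modified-ellipsoid tumor volume and fold change,
  percent positive cells.
- **synthetic_data** — ground-truth panel simulator: random 4PL single-agent
  curves plus fixed-ratio combinations constructed to carry a constant Loewe
  interaction index κ (so the pipeline's CI estimate can be checked against
  known truth), with multiplicative lognormal replicate noise and
  per-line/per-condition reproducible RNG streams.

## CLI

```sh
# generate a synthetic 28-line, 3-ratio panel with its ground-truth table
synscreen simulate --seed 1 --data-out panel.csv --truth-out truth.csv

# per-condition 4PL fit table
synscreen fit panel.csv -o fits.csv

# per-line CI profiles (E50-E80) and summaries
synscreen ci panel.csv --points-out ci_points.csv --summary-out ci_summary.csv

# full panel screen: fits, CI summaries, counts, optimal ratio, exclusions
synscreen screen panel.csv --outdir out/

# summary tables plus IC50 strip plot and CI box plot
synscreen report panel.csv --outdir report/
```

Input data are long-format CSV with columns
`cell_line, condition (PD|AZ|COMBO), ratio ("0.25:1" for combos, blank
otherwise), dose_uM, replicate, viability_pct`.  Combination series are
parameterised on the AZ-component concentration; the PD component equals the
ratio times the listed dose.  Analysis thresholds, effect grid and the
extrapolation limit can be overridden with a YAML config passed via
`--config` (see `ScreenConfig`).

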