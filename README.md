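# npk3414

Analysis toolkit for **'3414' NPK formula-fertilization field trials** — the
three-factor (N, P2O5, K2O), four-level, fourteen-treatment incomplete
factorial used by China's soil-testing / formula-fertilization programme to
calibrate fertilizer recommendations for a crop and locality. It is written
for agronomists and biostatisticians who have a plot-level yield table from
such a trial and want the full standard analysis:

* **design construction and trial I/O** — the 14-treatment ladder from the
  locally optimal (level-2) doses; CSV plot tables with per-treatment means;
* **quadratic fertilizer effect functions** — OLS fits of
  `Y = b0 + Σ b_i x_i + Σ b_ii x_i² + Σ b_ij x_i x_j` (doses in g/plant) over
  one, two or three nutrients, with R², the overall F test, stationary
  (maximum-yield) doses, and the *typicality* verdict: a function obeys the
  law of diminishing returns iff every linear coefficient is positive and
  every pure quadratic coefficient negative;
* **marginal economic optimum** for typical functions (marginal yield value =
  nutrient price), with a typed refusal for atypical ones;
* **abundance indices and economics** — relative yields of omission
  treatments, soil-nutrient abundance classes, per-gram yield gains, output
  value / fertilizer cost / profit-to-investment ratio per treatment;
* **yield-frequency dose recommendation** — when the fitted surface is
  atypical, count plots per nutrient level inside a target yield band and
  report the frequency-weighted mean dose, SD, SE and 95% CI as the
  recommended range;
* **synthetic trials** — simulate from a known quadratic surface with
  Gaussian plot noise and verify parameter recovery.

The package follows scikit-learn conventions: `QuadraticEffectModel` and
`FrequencyDoseRecommender` are estimators with `fit`/`predict` and
`get_params`/`set_params`; module-level functions are thin wrappers. A
canonical fixture — a published honeysuckle (*Lonicera japonica*) '3414'
trial, 14 treatments × 3 plots, level-2 doses (30, 10, 16) g/plant — ships in
`npk3414.datasets` and drives the test suite.

## Worked example

```python
import npk3414 as nk
from npk3414.datasets import canonical_trial, default_prices

trial = canonical_trial()          # 42 plots + published treatment means
prices = default_prices()          # 24 CNY/kg crop; 4.8/6/8 CNY/kg N/P2O5/K2O

# 1. Three-factor effect function on the 14 treatment means
surface = nk.fit_effect_function(trial, factors=("N", "P", "K"))
print(round(surface.r_squared_, 4), round(surface.p_value_, 4))
print(surface.typicality())
```

```
0.9881 0.0017
TypicalityVerdict(is_typical=False, violations=(('N_linear', 'positive', -0.7491920682937099),))
```

The surface fits tightly (R² = 0.9881, p = 0.0017) but is **atypical** — the
N linear term is negative — so the marginal-derivative optimum is refused and
recommendation proceeds by frequency analysis:

```python
# 2. Frequency analysis inside the yield band [296, 413] g/plant
rec = nk.recommend_doses(trial, nk.YieldInterval(296, 413), surface)
for f in "NPK":
    s = rec.summaries[f]
    print(f, s.table.counts, round(s.mean, 2), round(s.sd, 2),
          (round(s.ci[0], 2), round(s.ci[1], 2)))
print(round(rec.predicted_yield, 2))
```

```
N (5, 9, 24, 3) 24.15 12.04 (20.46, 27.83)
P (5, 9, 24, 3) 8.05 4.01 (6.82, 9.28)
K (5, 9, 24, 3) 12.88 6.42 (10.91, 14.84)
392.29
```

Per nutrient: in-band plot counts by level, weighted mean dose, SD, and the
recommended 95% range (g/plant); the last line is the fitted surface evaluated
at the three mean doses. Evaluating the trial's published surface at its
published point doses instead gives the headline optimized yield:

```python
from npk3414.datasets import published_ternary_model
print(round(published_ternary_model().evaluate((22.5, 7.5, 12)), 2))  # 386.95
```

```python
# 3. Economics (output value, cost, profit-to-investment ratio per treatment)
print(nk.economics_report(trial, prices).round(2).head(3).to_string(index=False))
```

```
 number treatment  mean_yield  increase_vs_control_pct  output_value  fertilizer_cost  ratio  usd_gain_vs_control
      1    N0P0K0      295.77                     0.00          7.10             0.00    NaN                 0.00
      2    N0P2K2      338.53                    14.46          8.12             0.19  43.22                 0.14
      3    N1P2K2      389.70                    31.76          9.35             0.26  35.97                 0.31
```

The same pipeline runs from the shell:

```sh
npk3414 run-all --out-dir reports/        # abundance, economics, fits, recommendation
npk3414 fit --factors P --treatments 4-7  # single-factor P effect function
npk3414 recommend --interval 296:413 --quantile normal
npk3414 simulate --surface surface.json --sd 5 --reps 3 --seed 42 --out trial.csv
```

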