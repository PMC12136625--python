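# Methods

## The '3414' design and the canonical trial

The '3414' scheme is the three-factor (N, P as P2O5, K as K2O), four-level,
fourteen-treatment incomplete factorial prescribed by China's soil-testing /
formula-fertilization technical specification. Level 2 is the locally optimal
dose; levels 0, 1, 3 are 0×, 0.5×, 1.5× of it. The fourteen treatments are the
control N0P0K0, the full-fertilizer reference N2P2K2, one omission treatment per
nutrient (level 0 for it, level 2 for the others), a four-point dose ladder per
nutrient with the other two fixed at level 2, and four lower-level combinations.

The packaged canonical fixture is a four-year-old honeysuckle (*Lonicera
japonica*) trial on the Loess Plateau: level-2 doses (30, 10, 16) g/plant,
three replicate plots per treatment, fresh-bud yield in g/plant, crop price
24 CNY/kg and nutrient prices 4.8 / 6 / 8 CNY/kg (0.1376 USD/CNY). It is
stored at two granularities because its source prints them inconsistently:
integer plot yields (42 plots, used for frequency counting) and two-decimal
treatment means (used for regression and economics). The means differ from the
plot averages in the second decimal (e.g. 378.5 vs 378.67), and one treatment's
mean is printed as both 338.5 and 338.53 in different tables; 338.53 is stored
because only it reproduces the fixture's own economics row. `canonical_trial()`
attaches the two-decimal means by default; `canonical_trial(means="plots")`
recomputes them from the plots.

## Quadratic fertilizer effect functions

The effect function over k ∈ {1, 2, 3} nutrients is

    Y = b0 + Σ b_i x_i + Σ b_ii x_i² + Σ_{i<j} b_ij x_i x_j,

with doses x in g/plant, *not* coded levels — the fitted three-factor
intercept (≈296.5) reproduces the unfertilized mean (295.77), which pins the
parameterization. Coefficients are ordinary least squares via `numpy.linalg.lstsq`
on either treatment means (default) or plots; on a balanced trial both give
identical coefficients, which the tests assert. A rank check raises a named
error when the dose design cannot identify all 1 + 2k + k(k−1)/2 coefficients.
Goodness of fit is R² plus the overall regression F test with (p−1, n−p)
degrees of freedom and an upper-tail p-value from the F distribution.

Sub-fits condition on the fixture's published treatment subsets (single-factor
N: treatments 2, 3, 6, 11; P: 4–7; K: 6, 8–10; two-factor NP: 2–7, 11, 12;
NK: 2, 3, 6, 8–11, 13; PK: 4–10, 14), exposed as an explicit
`treatments` filter so any other conditioning is reproducible.

**Typicality.** A fit is *typical* (law of diminishing returns) iff every
linear coefficient is strictly positive and every pure quadratic coefficient is
strictly negative; a zero coefficient counts as a violation (the boundary of a
strict sign rule). Each breach is recorded as (term, expected sign, observed
value).

**Stationary point.** ∇Y = 0 is solved through the Hessian H (2·b_ii diagonal,
b_ij off-diagonal); for one factor this is the vertex −b₁/(2·b₁₁). The point is
a maximum iff H is negative definite (eigenvalue test). The solver refuses when
cond(H) > 1e12 and verifies the gradient norm at the solution below 1e-9
(relative to ‖b‖). Doses are reported unrounded; rounding to printed precision
happens only in report formatting.

**Marginal economic optimum.** For a typical fit, the dose where each
nutrient's marginal yield value equals its price: ∂Y/∂x_i × crop_price =
nutrient_price_i (both per kg, so the ratio is unit-free and doses stay in
g/plant). Atypical fits raise a typed error — the canonical trial's
three-factor fit has a negative N linear term, so dose recommendation falls
back to frequency analysis, and the pipeline encodes exactly that branch.

## Abundance indices and economics

Relative yield = omission mean / reference mean. Abundance classes use
lower-inclusive bins — [0, 50%) extremely low, [50, 75%) low, [75, 95%) medium,
[95%, ∞) high — since the verbal ranges carry no boundary rule; the bins
partition [0, ∞) so every relative yield maps to exactly one class. Per-gram
gain = (reference − omission) / level-2 dose. Pairwise combination gain = the
relative increase over the control of the treatment supplying exactly that pair
at level 2, ranked descending with ties broken in the fixed order PK, NP, NK.

Economics (per plant): output value = yield × crop price / 1000; fertilizer
cost = Σ dose × nutrient price / 1000; profit-to-investment ratio = output
value / cost, undefined (typed error; NaN in reports) for the zero-cost
control. The USD gain versus control is the *gross* output-value gain,
(treatment − control) × USD crop price / 1000, with no cost subtraction —
that definition is what reproduces the fixture's headline 0.3729 USD/plant.
Computations are native CNY; USD views multiply by the schedule's conversion.

## Yield-frequency dose recommendation

When the effect function is atypical, the recommended dose comes from
frequency analysis. Per nutrient, count the replicate plots whose yield falls
in a target band, grouped by the plot's level of that nutrient, then

    x̄ = Σ u_j n_j / Σ n_j,   S = sqrt(Σ n_j (u_j − x̄)² / (Σn_j − 1)),
    SE = S / √Σn_j,          CI = x̄ ± q·SE,

with u_j the dose at level j. Decisions baked into the defaults, each a user
parameter:

* **Counting unit** is the individual plot (42 in the fixture), not the
  treatment: only plot counting reproduces the fixture's frequency totals
  (41, one control plot at 295 falling below the band).
* **Band** [296, 413] both-inclusive: the rounded minimum treatment mean up to
  the maximum plot yield. The open band sometimes quoted alongside the fixture
  does not reproduce its own counts; the inclusive variant reproduces the P and
  K columns exactly. The fixture's N-count column (5, 9, 21, 2) is inconsistent
  with any rule that reproduces P and K (all three give 5, 9, 24, 3 here) and is
  excluded from count-level tests.
* **Quantile** q: normal 1.96 by default — every published range has half-width
  1.96 × SE — with Student-t (Σn_j − 1 df) as an option, documented as giving
  slightly wider ranges.
* `weighted_sd` and `confidence_interval` accept externally supplied
  mean/SD so published intermediates (means 22.5/7.5/12, SDs 13.17/4.05/6.40)
  can be pushed through the downstream formulas verbatim; the fixture's printed
  means disagree with the mean formula applied to its own counts (which gives
  23.11/8.05/12.88), so they serve as fixed inputs only.

The recommendation bundles the per-nutrient summaries with a predicted yield:
the three-factor effect function evaluated at the point doses (the weighted
means, or an explicit override such as the published (22.5, 7.5, 12), which
gives 386.95 g/plant under the published function).

## Synthetic trials and parameter recovery

`simulate_trial` draws plot yield = true-surface value + independent
zero-mean Gaussian noise, floored at zero (with a truncation warning).
Defaults emulate the canonical trial: the (30, 10, 16) design, 3 replicates,
plot SD 5 g — the order of the fixture's replicate spread (±1–10 g). Noise is
homoscedastic and spatially unstructured; field trends, plot-size effects and
heteroscedasticity are deliberately not modeled, so passing recovery tests
demonstrate estimator correctness under the stated noise model, not robustness
to real field structure. Each plot's stream is seeded from (root seed,
treatment index, replicate index), so a seed fixes the trial and adding
replicates never perturbs earlier draws.

`parameter_recovery_report` simulates, refits, and reports per-coefficient
bias and RMSE plus the typicality-match rate. The packaged checks use 200
simulations at SD 5 for the bias/RMSE bounds (|linear bias| < 0.5 g/g,
intercept RMSE < 10 g — roughly three times the analytic sampling error at
n = 14 means), 20 paired-seed simulations for the replicate-monotonicity
check at 3/30/300 replicates, and 200 replicates for the recommendation
property: each nutrient's recommended range overlaps the band of doses whose
conditional yield (other nutrients at the surface vertex) is within 5% of the
maximum, in ≥90% of trials. The overlap — rather than containment-of-vertex —
form is deliberate: the frequency CI is centred on the design's level-2-heavy
weighted mean dose and is a recommendation band, not a vertex estimator.

## Numerical and interface choices

* Least squares by `lstsq` (SVD); tests cross-check every fixture fit against
  an independent Moore–Penrose pseudoinverse solution at 1e-8.
* R² is reported as the coefficient of determination; it is invariant under
  affine rescaling of the yield unit (property-tested).
* Trial tables are UTF-8 CSV with a header; treatment codes parse from the
  compact "N2P3K2" form (case/separator tolerant) or a level triple. Parse
  errors name the offending row. Reading a written table is the identity on
  plots and computed means.
* The CLI (`npk3414`) wires the stages as subcommands (`design`, `fit`,
  `indices`, `economics`, `recommend`, `simulate`, `run-all`) over a YAML
  config validated by a pydantic schema that rejects unknown keys; flags
  override config. Exit codes: 0 success, 2 validation error, 3 computation
  error. `run-all` emits a deterministic report bundle (CSV/JSON) — two runs
  with the same inputs are byte-identical.

## Known limitations

* Published coefficients of the fixture's three-factor function differ from
  the package's refit in the second decimal (e.g. N linear −0.75 vs −0.81);
  the source's rounding pipeline is unknown, so published-value checks use the
  published coefficients as *inputs* where the quantity is defined by them.
* The fixture's published N frequency column, weighted means, and the
  single-factor N "maximum dose 7.5" / K "maximum yield 445.99" entries are
  internally inconsistent with its own formulas; the package computes the
  self-consistent values (vertex 37.5 for N; 5, 9, 24, 3 counts) and treats
  the published figures as unreproducible.
* No mixed-effects or spatial field models, no post-hoc multiple-comparison
  letters, no cross-validation; significance is the overall regression F test.
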