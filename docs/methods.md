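# Methods

`pscea` implements a three-state cost-effectiveness model comparing
toripalimab plus chemotherapy against placebo plus chemotherapy as first-line
treatment of advanced NSCLC without EGFR/ALK driver mutations, from the
Chinese payer's perspective, together with the survival-curve fitting stage
that produces its inputs and the sensitivity-analysis machinery around it.
This note records the model, its assumptions, the parameter choices, and the
places where the published analysis had to be reverse-engineered.

## The decision model

**States and occupancy.** Patients occupy one of three states: progression-free
(PFS), progressive disease (PD), dead. Occupancy is *partitioned-survival*
("area under the curve"): at each cycle boundary `t_k`,

    PFS(t_k)  = S_PFS(t_k)
    Dead(t_k) = 1 - S_OS(t_k)
    PD(t_k)   = S_OS(t_k) - S_PFS(t_k)   (clamped at 0)

where `S_OS` and `S_PFS` are the fitted Weibull curves. This is the standard
construction when only OS and PFS curves are available; because the two curves
are fitted independently they can cross, so PD is clamped at zero and a
warning is logged when clamping touches more than 5 % of cycles. The occupancy
rule is isolated in `cohort.run_trace` so a transition-probability variant can
be swapped in.

**Survival inputs.** Each curve is a Weibull AFT model with location
`intercept` and `log_scale` (the `survreg` parameterisation); shape
`γ = exp(-log_scale)`, rate `λ = exp(-γ·intercept)`,
`S(t) = exp(-λ t^γ)`. Shape and rate are always recomputed from the AFT pair
(more digits survive in the printed intercepts); the printed shape/rate values
serve only as a consistency check. The time unit is nowhere stated in the
source; months (1 month = 30.4375 days) is adopted because it puts the
model-implied median PFS for the control arm (≈ 6.1 months) near the trial's
reported 5.6 months, whereas weeks or cycles are wildly inconsistent. The unit
is carried on every parameter object and is configurable.

**Cycles, horizon, discounting.** 3-week (21-day) cycles over a 10-year
horizon: `N = ceil(10 × 365.25 / 21) = 174` cycles. Half-cycle correction is
trapezoidal — per-cycle accrual uses the mean of the adjacent boundary
occupancies — applied to both QALYs and recurring costs. Costs and QALYs are
discounted at 3 %/year continuously in exact elapsed years, evaluated at the
cycle midpoint (`(1.03)^-(k+½)·Δt`); boundary factors are exposed as
`discount_factor`. With the correction disabled, membership at the cycle start
and start-boundary discounting are used instead.

**Utilities.** 0.673 per year in PFS, 0.473 in PD, 0 when dead, shared
between arms (adverse-event incidence was similar between arms in the trial,
so no AE disutilities are modelled).

**Costs.** Cost items are data, not code: each carries value/range,
distribution family, state, arm, application (`per_cycle` or `one_off`),
start/stop cycles and a charging interval. Recurring items accrue at
`value / interval_days` per day of corrected state occupancy; one-off items
are charged once against the boundary occupancy of their state at their start
cycle. A `pd_cost_uptake` multiplier (default 1.0) scales recurring PD-state
costs for scenario analysis of partial uptake of subsequent therapy.

## Reverse-engineering the published cost rules

The source prints its cost table ("per cycle" prices) but not the application
rules, and its results table cannot be regenerated under the literal reading
(3-week charging, chemotherapy capped at the trial's 4–6 cycles). Three
features of the printed results pin down what the published model actually
did, and the packaged fixtures encode them:

1. **Recurring costs were charged monthly.** Back-calculated state costs
   overshoot the printed ones by a uniform factor ≈ 0.69 = 21/30.4375 when
   charged per 3-week cycle. Fixture items therefore use
   `interval_days = 30.4375`; the strict per-cycle reading is one config edit
   (`interval_days = 21`).
2. **Chemotherapy ran for the whole PFS duration.** The printed PFS-state
   cost offsets between populations equal (chemo price difference) × (full
   discounted PFS person-time) in *both* arms, not a 6-cycle slice; for
   non-squamous patients pemetrexed indeed continues into maintenance.
   Fixtures leave `stop_cycle` unbounded; a cap is a config edit.
3. **The squamous and non-squamous results reused the ITT survival curves.**
   All three populations print identical effectiveness and identical PD-state
   costs, and the cost offsets above are exact under the ITT curves.
   `builtin_choice01(pop)` returns each population's own published curves
   (the faithful data); `published_analysis(pop)` combines a population's
   cost table with the ITT curves and is the configuration that reproduces
   the published tables. With its own curves, the squamous population's
   incremental QALYs are ≈ 0.20 (ICER ≈ 35 k$/QALY) — the published 18,369
   $/QALY is only reachable through the shared-curve convention, which
   `CEAResults.icer_with_effect` also exposes directly.

Under the reproduction configuration all six per-arm cost totals land within
−11 %…−6 % of the printed values and all three ICERs within +5 %…+8 %.

**Known irreproducible cells.** The printed effectiveness block
(0.94 / 1.61 / Δ0.67 QALYs) cannot be regenerated from the printed survival
parameters by any standard occupancy construction: partitioned survival gives
0.89 / 1.43 / Δ0.54, and the naive Markov variant (all PFS exits enter PD, PD
deaths at the OS hazard) gives 1.00 / 1.78 / Δ0.78. The printed block sits
between the two and is internally inconsistent with the printed PD-state
costs (which imply ~40 % less PD person-time than the printed PD QALYs).
The corresponding acceptance tests assert the published values and fail;
they are deliberately left failing rather than loosened. The same applies to
the published tornado ranking (see below).

## Incremental statistics

ICER = ΔC/ΔE with standard CE-plane dominance labels ("dominant",
"dominated", "undefined" at ΔE = 0); NMB = WTP·ΔE − ΔC; a strategy is
cost-effective iff NMB > 0. The decision threshold defaults to $37,653/QALY
(3× 2021 GDP per capita; $25,100 = 2× GDP is also of interest). ICERs are
reported to the nearest dollar in tables.

## One-way sensitivity analysis

Every cost parameter (items sharing a `group`, e.g. hospitalization in PFS
and PD, move together) and both utilities are set to their low/high bounds in
turn — the printed ranges, which are ±30 % of base — and the ICER is
recomputed; rows are ranked by absolute spread. Utility bounds are clipped to
[0, 1]; when a bound would invert the `u_pd ≤ u_pfs` ordering the other
utility is dragged along minimally to keep the parameter set valid (a ≤ 0.003
effect on this fixture). Survival parameters are not varied, matching the
published analysis. On these inputs the PFS utility has the largest leverage
(±30 % on `u_pfs` moves ΔE by ≈ 17 %), ahead of any single cost row — which
is why the published ranking (drug cost first, chemotherapy second) is not
reproduced; that ranking does not follow from the published leverages either.

## Probabilistic sensitivity analysis

Per iteration, every cost group is redrawn from a gamma and each utility from
a beta distribution with mean at the base value and
`sd = (high − low)/(2·1.96)` — the printed ±30 % range read as a 95 %
interval, the commonest convention; `sd_rule = "range4"` gives the
`range/4` alternative. Method-of-moments parameterisation
(`shape = m²/s²`, `scale = s²/m`; `α = m·ν`, `β = (1−m)·ν`,
`ν = m(1−m)/s² − 1`, with a logged uniform fallback if `ν ≤ 0`). Draws are
independent across parameters, shared between arms where the parameter is
(utilities, chemotherapy, hospitalization); when a drawn `u_pd` exceeds the
drawn `u_pfs` (≈ 5 % of draws) it is clamped to it. Survival curves are fixed,
so the occupancy traces are computed once and only accrual is repeated —
1,000 iterations run in well under a minute. Everything is driven by one
`numpy` `default_rng(seed)`; identical seeds give identical output. The CEAC
reports the fraction of iterations with positive NMB over a
$0–60,000 grid in $1,000 steps (covering both published thresholds).

## Curve fitting (the input-generation stage)

The published inputs came from digitized Kaplan–Meier figures. The package
re-implements that stage for users with their own curves:

* `reconstruct_ipd` inverts a digitized curve into pseudo individual-patient
  records by tracking the running product-limit estimate and placing, at each
  coordinate, the integer event count that best matches it (within
  `1/initial_n`). Without a numbers-at-risk table, no censoring is assumed
  before the last coordinate; with one, the interval-by-interval shortfall
  between tracked and reported numbers at risk is censored uniformly within
  the interval (a simplified Hoyle–Henley-style scheme, not the full Guyot
  algorithm).
* `fit_weibull_ls` regresses `log(−log S)` on `log t` (exact on noiseless
  Weibull curves; R² reported).
* `fit_weibull_mle` maximises the right-censored Weibull likelihood by
  profiling: the rate has the closed form `n_events / Σ t^γ` given the shape,
  and the shape solves the 1-d score equation by bracketed root-finding to
  machine precision (gradient at the optimum is reported and is ≲ 1e-10).
  It is cross-checked in the tests against `lifelines.WeibullFitter`.

Because the original digitized coordinates are not published, this stage is
validated entirely against synthetic ground truth; the published parameter
table remains the authoritative input of the packaged decision model.

## Synthetic data

`simulate_ipd` draws Weibull event times by inverse transform
(`t = (−ln U/λ)^{1/γ}`) with optional administrative (fixed time) or
exponential (random) censoring; `km_estimate` wraps the lifelines
product-limit estimator; `digitize` samples a step curve on a grid, applies
multiplicative Gaussian noise, re-monotonizes by running minimum and clips to
[0, 1], emulating plot-digitizer error. Defaults mirror the published fits'
shape range (γ ≈ 1.2–2.3). What the generator does *not* emulate: correlated
OS/PFS sampling, delayed treatment effects or cure fractions, informative
censoring, and digitization error that is correlated along the curve — so
passing round-trip tests show the pipeline is self-consistent under the
model's own assumptions, not that real digitized trial curves are this clean.

## Numerical choices and degenerate inputs

* Cycle grid: 174 boundaries + 1; halving the cycle length changes totals by
  < 0.5 % (asserted).
* Restricted means use trapezoid integration with step ≤ 0.05 months
  (< 0.1 % from a fine-grid oracle).
* `icer` scale-invariance and the NMB sign flip at WTP = ICER are property-
  tested; ΔE = 0 returns a label, never a division error.
* Zero-variance or `fixed` distributions short-circuit to the base value, so
  a fully degenerate PSA reproduces the deterministic result bit-for-bit.
* Gamma draws with zero base are degenerate at 0; infeasible beta moments
  fall back to uniform on the printed range with a logged warning.

## Problem sizes

Defaults are the published study conditions: 174 cycles, 1,000 PSA
iterations, ±30 % one-way ranges. Fitting-stage validation uses cohorts of
200–5,000 subjects and 10 seeded replicates at n = 2,000 for the
parameter-recovery check (the estimator mean is held to 5 %; single
replicates carry ~2–3 % sampling sd on the shape).

## Limitations

* The cost-application rules are back-calculated from the published results,
  not stated by the source; the fixtures make them explicit and editable.
* No background (other-cause) mortality beyond the OS curve; no
  microsimulation; no >2-strategy frontier; no EVPI.
* Only the Weibull family is implemented (the parameter type carries a family
  tag reserved for extension).
* The published effectiveness block and tornado ranking are knowingly not
  reproduced (see above); the corresponding tests are red by design.
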