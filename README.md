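# pscea

Partitioned-survival cost-effectiveness analysis of **toripalimab plus
chemotherapy versus chemotherapy alone** as first-line treatment for advanced
non-small-cell lung cancer (NSCLC) without EGFR/ALK driver mutations, from
the Chinese payer's perspective — packaged as a reusable, tested Python
library for health-economics practitioners.

## What it models

A cohort moves through three health states — progression-free (PFS),
progressive disease (PD), dead — with occupancy read off Weibull fits to the
trial's overall-survival and progression-free-survival curves
(partitioned-survival / "area under the curve" membership):

    PFS(t) = S_PFS(t),   Dead(t) = 1 − S_OS(t),   PD(t) = S_OS(t) − S_PFS(t)

Each curve is a Weibull AFT model (shape γ = exp(−log scale),
rate λ = exp(−γ·intercept), S(t) = exp(−λ t^γ), time in months). The model
runs 174 three-week cycles (10 years) with trapezoidal half-cycle correction
and 3 %/year discounting, accrues per-state costs and utilities
(u_PFS = 0.673, u_PD = 0.473 per year), and reports

* **ICER** = ΔCost / ΔQALY and **NMB** = WTP·ΔQALY − ΔCost, with the
  willingness-to-pay threshold WTP = $37,653/QALY (3× GDP per capita, 2021);
* one-way (tornado) sensitivity over every priced parameter ±30 %;
* probabilistic sensitivity (1,000-iteration Monte Carlo; gamma-distributed
  costs, beta-distributed utilities) with CE-plane scatter and
  cost-effectiveness acceptability curves;
* the survival-curve-to-parameters stage: pseudo individual-patient-data
  reconstruction from digitized Kaplan–Meier coordinates and Weibull fitting
  by least squares (on log(−log S) vs log t) or censored maximum likelihood;
* a seed-deterministic synthetic survival-data generator for validating the
  fitting stage against known ground truth.

All published inputs ship as editable JSON fixtures (three populations:
intention-to-treat, squamous, non-squamous; two arms each).
`builtin_choice01(pop)` loads a population's own published survival models;
`published_analysis(pop)` loads the configuration that regenerates the
published result tables (the published subgroup analyses reused the ITT
survival curves — see `docs/methods.md` for how the packaged cost rules were
back-calculated, and which published cells are knowingly irreproducible).

## Worked example

```python
from pscea import CostEffectivenessModel, published_analysis

spec, settings = published_analysis("ITT")
results = CostEffectivenessModel(spec, settings).fit()
print(results.summary())
```

```
Cost-effectiveness results
==============================================================
population:        ITT
cycle / horizon:   21 days x 174 cycles (10 y), discount 3.0%/y
--------------------------------------------------------------
                               placebo     toripalimab
cost, PFS state ($)              8,232          19,180
cost, PD state ($)               4,855           6,316
total cost ($)                  13,087          25,496
total QALYs                      0.888           1.427
--------------------------------------------------------------
incremental cost:  $12,409
incremental QALYs: 0.539
ICER:              23,028 $/QALY
NMB at $37,653/QALY: $7,881  ->  cost-effective
```

Adding toripalimab costs an extra $12,409 per patient over ten years and
yields 0.539 additional quality-adjusted life-years, i.e. $23,028 per QALY
gained — under the $37,653/QALY threshold (positive net monetary benefit of
$7,881), so the combination is cost-effective for the ITT population; the
same holds for both histology subgroups.

Sensitivity analyses hang off the same model:

```python
model = CostEffectivenessModel(spec, settings)
tornado = model.one_way()              # TornadoTable, .to_frame() / .plot()
psa = model.run_psa(n_iter=1000, seed=1)
psa.acceptability()                    # 0.992 at $37,653/QALY
curve = psa.ceac()                     # acceptability vs WTP grid
```

Or from the shell:

```bash
pscea basecase --population squamous --out out/
pscea dsa --population ITT --plot --out out/
pscea psa --n 1000 --seed 1 --plot --out out/
pscea fit --curve my_km.csv --risk-table my_risk.csv --n 300 --method mle --out out/
```

Every command writes CSV outputs plus a `manifest.json` recording inputs,
seed and package version.

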