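# depsurv

Net survival of cancer patients — the survival that would be observed if the
cancer were the only cause of death — is estimated in the *relative survival*
setting by subtracting each patient's expected (background) mortality, read
from general-population life tables, from their observed mortality.  National
life tables are usually stratified by sex, age, calendar year and region but
**not** by socio-economic position.  Because background mortality carries a
strong social gradient, analyses of the deprivation gap in net survival that
use unstratified tables attribute part of that background gradient to the
cancer itself and overstate the social gradient in cancer-specific outcomes.

`depsurv` is a toolkit for quantifying and correcting this bias:

* **Life tables** (`depsurv.lifetables`) — validated gridded mortality rates
  with exact piecewise-constant integration of the expected cumulative hazard
  `Λ_P(t)` along each patient's (age + t, year + t) diagonal.
* **Simulated deprivation-specific life tables** (`depsurv.lt_simulation`) —
  transfer the mortality gradient of an external source (five deprivation
  quintiles, or twenty income vingtiles aggregated 1–4, 5–8, …, 17–20) onto a
  base table by rate-ratio multiplication, with year carry-forward.
* **Non-parametric net survival** (`depsurv.netsurv`) — the Pohar–Perme
  estimator with exact event-time handling, age-standardized net survival
  (ICSS-style weights) and the Q1–Q5 *deprivation gap* at a horizon with a
  delta-method 95% CI.
* **Flexible excess hazard models** (`depsurv.excess_model`) — penalized
  tensor-product spline regression of the excess mortality hazard
  `λ(t, age, EDI, z) = λ_E(t, age, EDI) + λ_P(age+t, year+t, z)`, four
  candidate deprivation-effect forms (none / proportional / time-dependent /
  time- and/or age-dependent), corrected-AIC (AICc) selection, and excess
  hazard ratio (EHR) curves versus EDI and versus time (p90 = 4.4 against
  p10 = −3.9 of the European Deprivation Index).
* **Synthetic registry cohorts** (`depsurv.synthetic_data`) — cohorts with a
  known deprivation-graded background hazard and a configurable excess-hazard
  EDI effect, all with closed-form ground truth.
* **Comparison pipeline** (`depsurv.pipeline`) — run the same cohort under
  the original and the simulated deprivation-specific tables, and classify
  the sensitivity results as consistent / attenuated / inconsistent /
  inversed.

## Worked example

Simulate a registry-like cohort of 20 000 tumors in which deprivation has
**no effect whatsoever on the cancer's excess mortality**, but background
mortality rises across EDI quintiles (rate ratio Q5/Q1 = 1.5).  Then estimate
the 5-year deprivation gap — the difference in age-standardized net survival
between the least (Q1) and most (Q5) deprived quintiles — under both life
tables:

```python
from depsurv import SimulationConfig, gen_truth_tables, gen_cohort, deprivation_gap

cfg = SimulationConfig(n=20_000, background_rr=(0.85, 0.92, 1.00, 1.12, 1.275))
base, strat, _ = gen_truth_tables(cfg)
cohort, truth = gen_cohort(cfg, strat, seed=1)

for label, lt in [("original (unstratified)", base), ("deprivation-specific", strat)]:
    gap = deprivation_gap(cohort, lt, horizon=5.0)
    print(f"{label:26s} 5-year gap = {gap.gap:5.2f} pp  (95% CI {gap.ci_low:.2f}; {gap.ci_high:.2f})")
```

```
original (unstratified)    5-year gap =  4.24 pp  (95% CI 1.22; 7.26)
deprivation-specific       5-year gap = -0.34 pp  (95% CI -3.43; 2.75)
```

The unstratified table manufactures a spurious gap of about four percentage
points — deprived patients die more of *other* causes, and without a
deprivation-stratified life table that excess is misread as cancer-related —
while the correct table recovers a gap indistinguishable from zero.

A command-line interface mirrors the library:

```bash
depsurv gen-data --seed 7 --out cohort.csv --lt-base base.csv --lt-strat strat.csv
depsurv simulate-lt --base base.csv --source external.csv --vingtiles --out sim_lt.csv
depsurv compare --cohort cohort.csv --lt-main base.csv --lt-sim SA=sim_lt.csv --out report/
```

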