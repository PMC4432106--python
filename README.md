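# toxkinsim

Simulation–estimation studies of systemic exposure in rodent
toxicology: how accurately do composite/serial non-compartmental
summaries and population (nonlinear mixed-effects) modelling recover
AUC, Cmax and time-above-threshold from the sparse sampling schemes of
standard chronic-toxicity protocols?

Safety thresholds such as the NOAEL rest on exposure estimates taken
from toxicokinetic satellite and main-study groups, usually via naïve
pooled ("composite") profiles and non-compartmental analysis.
`toxkinsim` rebuilds that workflow in silico so the error of each
analysis choice can be measured directly: it simulates virtual
studies under known population PK models, analyses each simulated
study with both method families, and summarizes bias and precision
against the simulated truth over replicates.

## What's inside

* **Population PK simulation** — three structural models with
  first-order oral absorption: one-compartment with linear
  elimination (KA 13.46 h⁻¹, V 49.4 ml/kg, CL 2.72 ml/h/kg),
  one-compartment with Michaelis–Menten elimination (VMAX 2.72
  mg/h/kg, KM 1 mg/ml — saturating at the top dose), and a
  two-compartment model with slow accumulation; log-normal
  between-subject variability and 15 % proportional residual error.
* **Study designs** — 1-week / 1-month / 3-month cohorts, dose groups
  0/10/30/100 mg/kg/day, serial satellite profiles and random
  composite slot allocation under an equal-sampling constraint.
* **Exposure measures** — AUC₂₄ = ∫ₜ₋₂₄ᵗ Cp dt, Cmax₂₄,
  TAT = ∫ 1{Cp > thresh} dt, and model-predicted 6-month cumulative
  AUC and Cmax.
* **NCA estimators** — linear-logarithmic trapezoidal AUC, observed
  Cmax, interpolated TAT, on pooled composite means (arithmetic or
  geometric) or per-animal serial profiles.
* **FOCE-I estimator** — a from-scratch first-order conditional
  (with interaction) mixed-effects fitter with empirical-Bayes
  modes, an objective that is exact for Gaussian-conjugate cases, a
  covariance step with delta-method standard errors, and convergence
  bookkeeping.
* **Evaluation** — replicate orchestration with per-replicate
  truth, SMRE = (1/N)·Σ(est−true)/true·100 and the study CV formula
  (1/N)·√Σ((est−mean)/mean)²·100, quantile summaries, and
  convergence/covariance rates.

## Worked example

```python
import toxkinsim as tk

cfg = tk.ScenarioConfig(
    model_id="ONE_CMT",        # one-compartment reference compound
    duration="3_MONTHS",       # 91 days of daily dosing
    dose_group=30.0,           # mg/kg/day group to analyse
    n_replicates=10,
    master_seed=20150414,
)
table = tk.run_study(cfg)
print(table.summary[["method", "measure", "smre", "cv", "n_used"]]
      .to_string(index=False, float_format="%.3f"))
```

prints (10 replicates, seed 20150414; about two minutes on one core):

```
               method  measure   smre    cv  n_used
                MODEL    auc24 -3.143 0.857      10
                MODEL cauc_6mo -3.102 0.855      10
                MODEL   cmax24 -1.436 0.578      10
                MODEL cmax_6mo -1.436 0.578      10
                MODEL    tat24  0.000 0.000      10
NCA_COMPOSITE_GEOMEAN    auc24  2.690 2.507      10
NCA_COMPOSITE_GEOMEAN   cmax24  2.487 3.166      10
NCA_COMPOSITE_GEOMEAN    tat24  0.000 0.000      10
   NCA_COMPOSITE_MEAN    auc24  5.798 2.679      10
   NCA_COMPOSITE_MEAN   cmax24  4.251 3.279      10
   NCA_COMPOSITE_MEAN    tat24  0.000 0.000      10
   NCA_SERIAL_GEOMEAN    auc24 -6.492 2.188      10
   NCA_SERIAL_GEOMEAN   cmax24  7.147 2.865      10
   NCA_SERIAL_GEOMEAN    tat24  0.000 0.000      10
      NCA_SERIAL_MEAN    auc24 -6.043 2.140      10
      NCA_SERIAL_MEAN   cmax24  8.022 2.967      10
      NCA_SERIAL_MEAN    tat24  0.000 0.000      10
```

Reading it: SMRE is percent bias against each replicate's simulated
truth, CV the study's precision metric (smaller is better; note its
1/√N scaling with replicates).  The model-based arm is less biased
and 3–4× more precise than every NCA arm; serial NCA over-estimates
Cmax systematically (+7 to +8 %) because the maximum of noisy samples
can only exceed the curve's true peak; TAT is saturated at 24 h for
this compound at 30 mg/kg (the 10 µg/ml threshold is always exceeded),
so all methods agree exactly.  Only the model-based arm can
extrapolate the 6-month cumulative AUC and Cmax.

A command-line interface wraps the same pipeline:

```bash
toxkinsim validate-design --duration 3_MONTHS
toxkinsim run --config scenario.yaml --replicates 50 --seed 7 --out results/
toxkinsim report --records results/..._records.csv --config results/..._config.yaml
```

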