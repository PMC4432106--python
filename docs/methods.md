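# Methods

`toxkinsim` is a simulation–estimation framework for asking a single
question: when a chronic rodent toxicology study is analysed for
systemic drug exposure, how much bias and imprecision do the standard
non-compartmental (NCA) summaries carry compared with a population
(nonlinear mixed-effects) analysis of the same sparse data?  Every
quantity the package reports is computed by running that experiment
in silico: simulate a virtual study, analyse it both ways, compare
against the simulated truth, repeat.

## Population PK models

Three structural models with first-order oral absorption cover the
common disposition behaviours of small-molecule NSAID-like compounds
in rodents:

| Model | Structure | Typical values (BSV CV%) |
|---|---|---|
| `ONE_CMT` | 1-compartment, linear CL | KA 13.46 h⁻¹ (50), V 49.4 ml/kg (16), CL 2.72 ml/h/kg (20) |
| `ONE_CMT_MM` | 1-compartment, Michaelis–Menten | VMAX 2.72 mg/h/kg (20), KM 1 mg/ml (–), KA 13.46 (50), V 49.4 (16) |
| `TWO_CMT` | 2-compartment, linear CL | KA 0.55 h⁻¹ (50), V 49.4 (16), CL 2.72 (20), K12 0.3 h⁻¹ (–), K21 0.053 h⁻¹ (2) |

All amounts are normalized per kg body weight, so doses in mg/kg,
volumes in ml/kg and clearances in ml/h/kg give concentrations in
mg/ml, directly comparable with KM.  The Michaelis–Menten parameters
equal the linear model's clearance in the low-concentration limit
(CL = VMAX/KM), and saturate visibly at the 100 mg/kg/day dose, so the
two scenarios differ only by the nonlinearity.  The two-compartment
rate constants produce slow accumulation that approaches steady state
after roughly two weeks of daily dosing.  The `TWO_CMT` K21 value and
its BSV are constructor arguments because the reference value admits
more than one reading; 0.053 h⁻¹ with 2 % BSV is the default.

Between-subject variability is log-normal with the NONMEM convention
ω = CV/100 on the log scale (at these CVs the difference from
ω² = ln(1+CV²) is under 1 %).  Residual error is proportional,
`y = f·(1+ε)`, ε ~ N(0, σ²) with σ = 0.15.  Bioavailability is fixed
at 1 with no lag time; neither is informative here because dose and
volume are only identified jointly anyway.

Closed forms (stabilized against the KA → ke coincidence through a
`phi(x) = (1-e^{-x})/x` formulation) handle the linear models under
dose superposition; the Michaelis–Menten system is integrated with
LSODA at rtol 1e-8 / atol 1e-10, with the cumulative AUC and the
eliminated amount carried as extra states so that exposure and mass
balance come from the same solve.  An observation scheduled exactly at
a dose time is evaluated just before the bolus (pre-dose trough).

## Study designs

Three standard chronic-toxicity cohorts share dose groups of 0, 10,
30 and 100 mg/kg/day by daily oral gavage:

| Duration | Main (toxicity) group | Satellite group | Sampling days |
|---|---|---|---|
| 1 week (7 d) | 4/group, composite | 3/group, serial | day 1 |
| 1 month (28 d) | 10/group, composite | 3/group, serial | days 1, 28 |
| 3 months (91 d) | 12/group, composite | 3/group, serial | serial days 1, 28, 91; composite days 28, 91 |

Within-day sampling times are 0.1, 0.4, 1, 1.5, 4, 8 and 24 h after
that day's dose.  Serial sampling draws the full 7-point profile from
every satellite animal.  Composite sampling covers each time point
with 3 animals drawn from the main group, allocated at random under
the constraint that per-animal sample counts differ by at most one;
the allocator serves time points in random order and assigns each to
the animals with the most outstanding slots (random tie-break), which
guarantees feasibility for balanced counts.  Calendar conventions:
1 month = 28 days, week 4 = day 28, week 13 = day 91, 6 months =
180 days — multiples of the 24-h interval so steady-state days align.
Composite days for the shorter cohorts follow the serial days; a
composite group of 8 animals and other variants are reachable through
design overrides.

The vehicle group is simulated (all observations exactly zero) but
excluded from estimation, which matches practice and avoids a
degenerate proportional-error likelihood.

## Exposure measures

Five measures are derived from noise-free predicted profiles: AUC24
(over the last full dosing interval of the evaluation day), Cmax24,
TAT24 (time above a threshold, default 0.01 mg/ml = 10 µg/ml — an
illustrative adverse-effect threshold), the 6-month cumulative AUC,
and the 6-month Cmax.  Linear models use exact per-dose integrals;
the Michaelis–Menten model reads the AUC state off the ODE solve.
Peaks are located by a grid scan refined with bounded scalar
minimization; threshold crossings by sign scanning plus Brent root
finding.  At the reference parameters the linear 30 mg/kg profile
never falls below 10 µg/ml at steady state, so TAT saturates at 24 h —
the threshold is configurable precisely so that non-degenerate TAT
scenarios can be exercised.

Replicate truth follows the `individual-mean` convention by default:
the mean of the analyzed group's per-animal exposures computed from
their realized parameters.  This is the quantity a perfectly measured
study of those animals would report.  A consequence worth knowing:
model-based estimates evaluated at fitted *typical* values sit about
ω²/2 ≈ 2 % below the mean-individual truth for lognormal clearances —
a real, small, structural offset, not an estimator defect.  The
`typical` convention is available as a config switch.

## Non-compartmental analysis

Composite arms pool the main group's observations per scheduled time
and summarize with the arithmetic or geometric mean (zeros are
excluded from geometric means, with the contributing count reported;
an all-zero time point is dropped).  Serial arms compute per-animal
AUC/Cmax/TAT and then average across animals.  AUC uses the
linear-logarithmic trapezoid: linear on rising or flat segments,
logarithmic on strictly decreasing positive segments.  TAT mirrors the
same interpolation convention, with crossings solved per segment in
closed form — the interpolation rule for TAT is this package's
decision, since discrete-sample TAT has no canonical definition.  A
t = 0 anchor is prepended to each profile: zero on day 1, the
profile's own 24-h trough on steady-state days (the end of the
previous interval equals the start of the current one), and nothing
when no trough sample survives filtering — the AUC then spans the
surviving grid.  No extrapolation beyond observed samples is
performed, which is why NCA reports no 6-month measures.

## FOCE-I estimation

The estimator is a from-scratch first-order conditional (with
interaction) implementation: per subject, the conditional mode η̂ of
the joint density is found and the marginal likelihood approximated by
Laplace with the Gauss–Newton (expected-information) curvature, the
residual variance σ²f² evaluated at the conditional prediction.  For
a model linear in η with additive error the objective equals the
exact Gaussian −2 log-likelihood, which the tests assert.  Random
effects sit on exactly the parameters that carry BSV, Ω diagonal; all
structural parameters, log random-effect SDs and log σ are estimated.
Subjects from all active dose groups and both roles are fit jointly —
the integrated analysis is the point of the method.  Animals whose
observations are all removed (e.g. below the LLOQ) are excluded with a
warning; below-LLOQ records are omitted, not imputed.

Numerics, chosen for a likelihood whose proportional-error surface is
sharply curved for sparse subjects:

* **Inner problem** — damped Newton over all subjects at once
  (vectorized), with analytic prediction Jacobians for the
  one-compartment model and finite differences otherwise; subjects
  still above tolerance after the sweep (typically 2-observation
  animals in curved valleys) are polished individually by BFGS.
* **Michaelis–Menten predictions** inside the likelihood integrate the
  central amount with a fixed-grid classical Runge–Kutta scheme, the
  depot handled analytically as a forcing term (exact, and immune to
  the stiffness of fast absorption); the grid is fine (0.01 h) through
  the absorption transient and coarse (0.2 h) after, giving ~1e-6
  relative accuracy against the adaptive reference solver at a small
  fixed cost.  This path requires single-dose-before-observation data
  (day-1 profiles); multi-dose Michaelis–Menten data fall back to the
  adaptive solver per subject.
* **Outer problem** — a box-constrained BFGS written for this
  objective: steps capped at 0.5 log-units per coordinate, geometric
  backtracking with simple-decrease acceptance (Wolfe-style cubic line
  searches collapse on the cliff-like regions far from the optimum),
  forward-difference gradients whose evaluations all share one
  warm-started set of conditional modes so systematic inner-solve
  offsets cancel, and periodic reconciliation against a cold-started
  solve.  Convergence ("successful minimisation") means a projected
  gradient below 1e-3, or a stalled search certified locally optimal
  by coordinate probes: no ±0.01 log-unit move improves the objective
  by more than 1e-3.
* **Covariance step** — central-difference Hessian of OFV/2 at the
  optimum; success requires positive definiteness, and standard errors
  map back through the log transform by the delta method.  Initial
  estimates default to the simulating values × 1.5, reflecting the
  assumption that the compound's PK is roughly known when the
  toxicology study is analysed.

Non-convergence is recorded in the result object, never raised, and
such replicates are excluded from bias/precision summaries while being
counted in the convergence and covariance rates.

## Replicate studies and metrics

A scenario (model, cohort, analyzed dose, replicate count, seeds,
LLOQ, threshold, methods) is run as independent replicates, each
seeded from the master seed through `SeedSequence` spawning — results
are identical however the loop is executed.  Per replicate the
dataset is simulated, BQL-filtered (default LLOQ 0.001 mg/ml, inert at
these exposures but exercised by tests), analysed by the NCA arms and
by one integrated FOCE-I fit, and converted to relative errors against
the replicate's own truth.  Across replicates:

* SMRE = mean of relative errors × 100 (bias, %);
* CV = sqrt(Σ((estimate − mean)/mean)²)/N × 100 (precision, %).

Note the 1/N *outside* the square root in CV: this printed definition
shrinks like 1/√N with the replicate count and is therefore not the
sample CV; it is reproduced exactly because it is the definition the
reported bounds refer to, and a `sample` convention switch is provided
and recorded in the output.

## Scale of the shipped experiments

The reference experiment uses 50 replicates of the 3-month
one-compartment scenario (the acceptance script and the test suite
share this scale; each replicate is a 45-subject FOCE-I fit, ~7 s).
The model-family comparison runs 5 replicates of a reduced 1-week
design (3+3 animals per group).  These sizes were chosen as the
smallest at which the Monte-Carlo summaries are stable enough to
compare against the reported performance bounds.

## What the generator does and does not emulate

Simulated studies assume a homogeneous rodent population (no
covariates), no inter-occasion variability, no dropout or missed
doses, perfectly executed sampling times, and a correctly specified
structural model shared by simulation and estimation.  Passing tests
therefore demonstrate estimator-class properties under no
misspecification — they do not certify performance on real data,
where model misspecification, covariate structure and larger residual
noise would add to every error reported here, disproportionately so
for extrapolated quantities (the 6-month measures).

## A note on composite vs serial precision

One directional expectation — that composite sampling is less precise
than serial sampling — holds here for Cmax but reverses for AUC.  The
reversal is not an implementation artifact: with the same total number
of samples, the composite arm pools observations from more animals
(12, or 8 in the reduced preset) whose between-subject variability
partially averages out across time points, while the serial arm
averages the exposures of only the 3 satellite animals; likewise a
population fit on many sparse subjects beats one on few rich subjects
for typical-value precision.  The Cmax direction survives because the
pooled-mean peak depends on which animals happen to cover the
absorption-phase time points, a noise source serial profiles do not
have.  The corresponding test asserts the original expectation for
AUC and is expected to fail under this generator; it is kept to make
the disagreement visible rather than hidden.

## Known limitations

* FOCE-I here is not NONMEM: convergence criteria and covariance
  options are documented substitutes, and agreement is statistical
  (parameter recovery, bias/precision), not OFV-digit equality.
* Ω is diagonal; correlated random effects are out of scope.
* No M3-style likelihood for below-LLOQ data (omission only), no
  SAEM, no covariate search, no model averaging.
* The printed-formula CV must not be compared across studies with
  different replicate counts (its 1/√N scaling is intentional).
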