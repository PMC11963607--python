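# Methods

This package evaluates neonatal amikacin dosing regimens against
PK/pharmacodynamic targets, end to end: a population pharmacokinetic engine,
MAP Bayesian estimation of individual exposure from sparse therapeutic drug
monitoring (TDM) samples, two dosing-regimen engines, an external-validation
battery, and cohort-level target-attainment summaries — exercised on
synthetic two-site cohorts because no patient data ship with the code.

## Structural and stochastic model

Disposition is a linear two-compartment model with zero-order infusion
input, parameterized by clearance CL (L/h), central volume V1 (L),
inter-compartmental clearance Q (L/h) and peripheral volume V2 (L).
Solutions are exact analytic superpositions of bi-exponential
infusion/post-infusion terms; setting Q = 0 (or V2 = 0) reduces the engine
exactly to the one-compartment closed form.  AUC over any window is
analytic (no quadrature), and total AUC equals dose/CL by mass balance —
both facts are used as oracles in the test suite, alongside an adaptive ODE
integration of the same system.

Typical values are modulated by a configurable product of covariate terms.
The shipped configuration (`src/neopta/data/population_model.yaml`) uses the
covariate structure established for amikacin in neonates — birth weight
(power, exponent 1.34) and postnatal age (linear slope) on CL, a fractional
reduction (−16%) under ibuprofen co-administration, and current weight
(power, exponent 0.919) on V1:

    CL = 0.084 L/h x (bBW/1750)^1.34 x (1 + 0.07 (PNA − 2)) x (1 − 0.16 IBU) x e^eta_CL
    V1 = 0.833 L  x (cBW/1760)^0.919 x e^eta_V1

Inter-individual variability (IIV) is log-normal on CL (omega = 0.25) and
V1 (omega = 0.30).  The IIV on V1 is not estimable from routine
trough-and-peak TDM (the posterior is dominated by the prior) and is
therefore *fixed* at 30%, a value in the range reported for neonatal
aminoglycoside models; the configuration marks it `fixed` and the
estimation code never updates fixed components.  Residual error is combined
proportional (10%) + additive (0.4 mg/L), a common choice for immunoassay
TDM data; concentrations below the 0.8 mg/L lower limit of quantification
(LLOQ) are flagged BLQ and retain their value for audit.

### Calibration of the numeric constants

The defaults were set once, by desk calibration, to reproduce published
neonatal amikacin kinetics rather than any particular dataset: V1 of about
0.47 L/kg; half-lives falling from roughly 12 h in extremely preterm
neonates in the first days of life to 3–8 h near term and with advancing
postnatal age; typical 1-h peaks of 25–35 mg/L under 15–16 mg/kg doses; and
troughs that straddle the 3 and 5 mg/L toxicity thresholds in the heavier,
shorter-interval dosing categories while falling near the LLOQ for preterm
neonates dosed every 36–48 h.  Q and V2 are kept small (0.05 L/h and
0.15 L at the reference size) so the peripheral compartment perturbs rather
than dominates the profile, and both are size-scaled with the V1 covariate
factor — the covariate grammar deliberately targets only CL and V1, and an
unscaled peripheral compartment would distort kinetics at the extremes of
the 420 g–5 kg weight range.  These constants are configuration, not code:
any transcription of a published parameter table can be dropped in.

## Dosing regimens

Two engines expand covariates into first-dose regimens, both shipped as CSV
tables loaded row-for-row:

* **complex**: ten categories by postnatal age (< 14 / >= 14 days) and
  current weight; 15–20 mg/kg every 20–48 h; interval + 10 h under
  ibuprofen.  The published table prints shared band edges
  ("800 to 1,200", "1,200 to 2,000"); this engine adopts
  lower-inclusive/upper-exclusive bands ([800, 1200), [1200, 2000),
  [2000, 2800), plus < 800 and >= 2800).  The alternative +6 h interval
  sometimes suggested for categories 7 and 9 is not applied, matching the
  evaluated practice.
* **simplified**: 15 mg/kg every 36 h below 30 weeks' gestation, every 24 h
  at or above; no ibuprofen rule (the published simplified table carries
  none).

Absolute amounts are mg/kg x current weight rounded to 0.1 mg.  Both
engines are total on the eligible domain (PNA 0–30 days) and reject older
infants.

## MAP estimation

For each subject the random effects eta = (eta_CL, eta_V1) minimize the
extended-least-squares objective

    sum_j [ (y_j − f_j(eta))^2 / sigma_j^2 + ln sigma_j^2 ] + eta' Omega^-1 eta,
    sigma_j^2 = (sigma_prop f_j)^2 + sigma_add^2,

over the non-BLQ observations, by L-BFGS-B from eta = 0 plus four ±0.5
perturbation starts.  BLQ records are excluded from the likelihood — the
simplest defensible default; an M3-type censored likelihood was considered
and deliberately left out of scope.  With no usable observations the prior
mode (eta = 0) is returned, so the individual collapses to the population
prediction; the objective at the estimate never exceeds the objective at
zero by construction.  Posterior variances come from the curvature of the
−2 log-posterior at the mode (central differences, step 1e-4) and feed the
shrinkage correction below.  First-interval Cmax (1 h after the start of
the first infusion), Cmin (immediately before the second dose) and AUC0–tau
are then evaluated at the MAP parameters.

## Population re-estimation (iterative two-stage)

Re-estimation alternates (i) MAP estimation of all subjects under the
current population values with (ii) parameter updates: each typical value
is multiplied by exp(mean eta-hat) (the geometric mean of individual over
typical parameters), and each free omega^2 is set to var(eta-hat) plus the
mean posterior variance, which corrects the downward shrinkage bias of the
raw eta-hat variance.  Iteration stops when every update changes by less
than 0.5% (relative) or after 50 iterations, in which case the last iterate
is returned flagged non-converged with a warning.  Components named
`fixed` — notably omega_V1 — are never touched.  Inside the iteration MAP
fits are warm-started from the previous eta-hat with a single start; the
public `map_estimate` default remains multi-start.

Iterative two-stage is a desk-scale method chosen for transparency and
speed; it approximates, and is documented as distinct from, full marginal
likelihood estimation (FOCE/SAEM) in dedicated mixed-effects software.
Parameter-recovery simulations (500 subjects, two samples each, five seeds)
recover the typical clearance within a few percent and omega_CL within
about 10–15%.  Recovery experiments sample at 1 h and mid-interval:
trough-heavy designs censor exactly the high-clearance subjects' troughs at
the LLOQ, and since BLQ records are excluded from the likelihood this
biases clearance recovery downward by ~15% — a genuine property of
BLQ-exclusion on censoring-heavy designs, not an optimizer artifact.

## Validation battery

* **Bias/imprecision**: prediction error is defined as prediction −
  observation, so a negative mean prediction error (MPE) reads as
  under-prediction.  MPE carries a t-interval CI; RMSE a seeded
  nonparametric bootstrap percentile CI (1,000 resamples).  RMSE >= |MPE|
  always.  Both population and individual predictions are reported,
  stratified by sample class (peak: < 2 h after a dose; trough: > 20 h).
* **NPDE**: per subject, K (default 1,000) full design replicates are
  simulated; observed and simulated vectors are decorrelated with the
  inverse Cholesky factor of the simulated covariance (marginal fallback
  with a warning if singular); the prediction discrepancy is the jittered
  rank of the decorrelated observation among the simulations, clipped to
  [1/(2K), 1 − 1/(2K)] and mapped through the normal quantile.  Mean-zero
  (t-test) and unit-variance (chi-square) tests are reported.  Calibration
  holds on self-simulated data when censoring is negligible; on
  trough-heavy designs the exclusion of BLQ records truncates the observed
  distribution from below and shifts the NPDE mean positive — the same
  mechanism by which the diagnostic flags model-data mismatch on real data.
* **VPC**: observations binned by quantiles of time after last dose
  (default 8 bins, bins under 5 observations merged); observed 5/50/95th
  percentiles against the 95% simulated band of each percentile.
* **IIV diagnostics**: Spearman correlation of eta_CL-hat with postnatal
  age, birth weight and current weight; a constant eta is reported as
  rho = 0 with a degenerate flag.
* **omega_V1 sensitivity**: the MAP assessment and attainment summary are
  re-run over a grid of fixed omega_V1 values in [0, 0.6]; widening
  omega_V1 widens the simulated peak-concentration distribution.

## Target attainment

Targets: Cmax >= 15, >= 24 and >= 35 mg/L (the last flags overexposure);
Cmin <= 3 and <= 5 mg/L; AUC0–tau/MIC >= 21.4 (bacteriostasis) and >= 62.5
(1-log10 reduction) for Enterobacterales at MIC 2, 4 and 8 mg/L (the
E. coli wild-type ECOFF).  All inequalities are inclusive.  AUC/MIC uses
the AUC over the actual dosing interval, matching the evaluated practice;
a per-24 h normalization exists but is off by default because intervals
differ between categories and the evaluation is explicitly per-interval.
Attainment >= 90% of a cohort (inclusive) is adequate.  The inclusive
construction makes the threshold chains monotone on every cohort.

## Synthetic cohorts

Site profiles match the two study populations' published summaries:
gestational age from a truncated preterm bulk plus a uniform term tail
(site A: median ~28.7 weeks, 12.5% term; site B: median ~34 weeks, 30%
term), integer postnatal ages from truncated lognormals (medians 9 and
2 days), birth weight from a log-linear gestational growth curve
(~1,100 g at 28.7 weeks, ~3,500 g at 40 weeks) with 15% lognormal spread,
current weight from birth weight via an early-loss/later-gain postnatal
factor, ibuprofen prevalence 2% and 5%, and all values clipped to the
published ranges.  Sampling schemes: both sites draw a trough 1 minute
before the second dose; site A draws its peak 1 h after the start of the
first infusion, site B 1 h after the start of the second.  Optional
±15 min sampling-time jitter is off by default.

The generator matches medians, ranges and prevalences — not joint
covariate structure (e.g., the real correlation between postnatal age and
weight gain is unknown from published summaries and modeled as simple
additive growth), nor pathophysiology (sepsis, asphyxia, renal
dysfunction).  Passing tests therefore demonstrate that the pipeline is
correct and well-calibrated under the stated generative model; they do not
certify predictive performance on real neonates.

Ground truth (eta, noise-free metrics) is persisted with every simulated
subject, making the generator the oracle source for round-trip tests.

## Numerical choices and problem sizes

Hours are the time unit, t = 0 at the first dose start.  The one-compartment
branch is taken exactly when Q·V2 = 0.  MAP convergence uses L-BFGS-B with
ftol 1e-10; the grid-search oracle in the tests scans eta in [−1, 1]^2 at
step 0.01.  Analyses run at 1,000 virtual neonates per site;
parameter-recovery at 500 subjects x 5 seeds; NPDE at K = 1,000 on ~1,000
observations; VPC at 200–300 replicates; the RMSE bootstrap at 1,000
resamples.  These sizes put every Monte Carlo error well below the decision
thresholds they support while keeping any single analysis in the minutes
range on one CPU.

## Known limitations

* Iterative two-stage updates only the components that carry IIV; covariate
  coefficients and residual SDs are taken as given (the analysis questions
  here concern typical values and IIV, not covariate selection).
* BLQ exclusion biases estimation on heavily censored designs (quantified
  above); an M3 censored likelihood is the natural extension.
* No inter-occasion variability; all occasions enter one MAP fit.
* The synthetic cohorts are summary-statistic emulations; conclusions about
  the real populations require the real TDM datasets.
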