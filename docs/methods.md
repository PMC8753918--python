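# Methods

This note documents the model implemented in `triagesim`: its structure,
parameters, the synthetic stand-ins it ships, numerical conventions, and the
design choices made where the design was genuinely open.

## Model structure

One simulated patient carries `(age, sex, ISS, GCS, trauma type)`. The model
is a decision tree (triage → destination → secondary transfer) followed by a
three-stage survival cascade and lifetime accrual:

- **Triage.** A tool classifies the patient positive with probability equal
  to its sensitivity if ISS ≥ 16 and 1 − specificity otherwise. Sensitivity
  and specificity describe the *final* scene decision, tool plus paramedic
  judgement.
- **Destination and transfer.** Tool-negative patients start locally and are
  transferred to an MTC with probability 32.5% (ISS ≥ 16) or 4.3% (ISS < 16).
  Tool-positive patients are MTC patients; with probability 26.6% (ISS ≥ 16)
  or 7.4% (ISS < 16) they are first stabilised locally and then transferred.
  This interpretation of the four transfer probabilities reconciles the
  model diagram's two-way arrows with the published per-category transfer
  rates and reproduces the published flow columns analytically: the expected
  ISS ≥ 16 MTC flow is `n16·(sens + (1 − sens)·0.325)`, e.g. 4,607 of 8,916
  for the (28.4%, 88.6%) tool. Patients reaching an MTC at any point receive
  the full MTC benefit; every transfer costs £252.
- **0–30 days.** `Ps = expit(b0 + b_age·age + b_ISS·ISS + b_GCS·GCS +
  b_male·male)`. Death probability `1 − Ps` is multiplied by RR 1.25 for
  ISS ≥ 16 patients who never reach an MTC (RR 1 for ISS < 16 by assumption).
  "Died before discharge" is operationalised as death within 30 days.
- **30 days–1 year.** Fixed probabilities 3.6% (ISS ≥ 16) / 1.7% (ISS < 16),
  the former ×1.64 for local-only care.
- **Beyond 1 year.** Annual Bernoulli walk over a life table with the
  severity hazard ratio applied on the hazard scale, `q' = 1 − (1 − q)^HR`
  (HR 5.19 for ISS ≥ 16, 1.38 below), capped at age 100 where q = 1.

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| Discount rate | 3.5%/yr | applied to QALYs and costs from year 1 |
| MAICERs | £20k, £30k/QALY | decision thresholds |
| Utility, ISS ≥ 9 at 1 yr | 0.65 | converts to multiplier 0.789 = 0.65/0.824 |
| Genpop utility regression | 0.9508566 − 0.0002587·age − 0.0000332·age² + 0.0212126·male | clipped to [0, 1]; never clips for ages 0–100 |
| MTC admission premium | £2,819 (ISS ≥ 16), £1,466 (9 ≤ ISS < 16), £0 (ISS < 9) | no tariff row exists below ISS 9, so no premium |
| Acute treatment | ISS-banded, blunt/penetrating | band edges follow the source tariffs literally, including the differing second-band edges (blunt 9 < ISS ≤ 16 vs penetrating 9 < ISS ≤ 15) |
| Post-discharge (≤ 6 mo) | £1,766 | charged to every 30-day survivor, including those dying before 6 months |
| Long-term cost multiplier | 1.45 (ISS ≥ 16), 1.25 (ISS < 16) | applied to all survivors, including ISS < 9 (literal reading of the grouped "ISS < 16" row); configurable |

## Synthetic inputs and what they do (not) show

Three inputs of the original analysis are not redistributable and ship as
clearly labelled synthetic stand-ins:

- **Cohort.** `cohort.sample_cohort` reproduces the registry's printed
  marginals exactly in expectation — age 46.8 ± 21.3 (truncated normal on
  [16, 100], parent moments solved numerically), ISS 5.2 ± 7.2 with
  P(ISS ≥ 16) = 0.091 (two-parameter exponential-family pmf on 1–15 plus a
  geometric tail on 16–75, all three shape parameters solved by
  root-finding so mean, SD and tail mass match; the tail's conditional mean
  is pinned at 24, a typical severe-trauma value), GCS 14.4 ± 1.9 (point
  mass at 15 plus a discretised-normal component centred near 8, matching
  the clinical pattern that roughly the severe fraction of patients have
  depressed consciousness), 58.3% male, 98.2% blunt. Dependence is a
  Gaussian copula with configurable latent correlations (defaults:
  ISS–GCS −0.4, ISS–age +0.1) — the real registry's joint structure is
  unknown, so dependence is configuration, not fact. Infeasible moment
  targets degrade to a least-squares best fit with a warning.
- **Survival equation.** The published 30-day coefficients are not printed in
  the open literature we can ship, so the default coefficients
  (b0 = 1.70, b_age = −0.035, b_ISS = −0.085, b_GCS = 0.30, b_male = −0.10)
  are *illustrative, TARN-like*: correct signs, and cohort 30-day mortality
  ≈ 4.4–4.7%, in the published 4–5% band. Any logistic form's coefficients
  can be supplied via `clinical.survival_model` in the YAML config.
- **Life table / NHS costs.** Gompertz–Makeham mortality
  (μ(x) = A + B·e^{0.1x}) with parameters solved to give period life
  expectancies at birth of 79 (male) / 83 (female); a quadratic age-cost
  curve (≈ £500/yr young adult → ≈ £3,000/yr at 90, men +5%). Real ONS/cost
  tables load from CSV.

Consequently: passing tests demonstrate the *mechanics* (flows, dominance
structure, orderings, convergence, exact reproduction of the analytically
derivable published quantities), not the published absolute QALY/cost/ICER
levels, which depend on the restricted inputs. The worked example's QALYs
(≈ 14.0) and costs (≈ £40k) differ from the published ≈ 13.6 / ≈ £33k for
exactly this reason; flows, death proportions and life years land close to
the published values because they depend mainly on printed parameters.

## Accrual and discounting conventions

The source specifies the discount rate but not the timing grid; we use
annual cycles from the injury year, t = 0 undiscounted, discount factor
(1 + r)^−t, and a half-year credit (utility and long-term cost) in the year
of death. Patients dying within 30 days accrue zero QALYs and no
post-discharge or long-term costs; deaths between 30 days and 1 year accrue
half a year of utility, the post-discharge cost, and no long-term costs
(year-0 care is covered by the acute and post-discharge components).
Survivors' first-year utility already carries the 1-year-post-injury
multiplier (no separate acute disutility). Life years are counted as whole
cycles survived plus the half death-year (0 / 0.5 / K + 0.5).

## PSA distributions

The published appendix distributions are not available, so the package uses
standard health-economics families, moment-matched so every distribution's
analytic mean equals its point estimate (deterministic run = PSA centre):
Beta for probabilities and the cohort utility, Gamma for costs, Lognormal
for RRs and HRs. The default standard error is 20% of the mean
(`psa.default_se_frac`); tool sensitivities/specificities are Beta with
effective sample sizes on the scale of the tool-derivation cohort (1,000
positives / 10,000 negatives, configurable). The general-population utility
regression coefficients, the assumption RR of 1, and economic settings stay
fixed. `default_se_frac: 0` degenerates the whole PSA to the point
estimates. Invalid draws are resampled with a warning. ICERs come from mean
costs and mean QALYs across runs, never from averaging per-run ICERs;
deterministic-mode ICERs are reported separately. Stability is assessed by
a running-mean check (converged when the last 10% of runs move the mean by
less than a tolerance).

## Common random numbers and reproducibility

Per-patient uniforms are split by purpose (triage, transfer, 30-day, 1-year,
long-term stream) and shared across all nine tools within a run, so
strategies differ only through their thresholds; parameter draws use a
separate stream per PSA run. Because the tools' positives nest as
sensitivity rises, common random numbers make per-run mean QALYs *exactly*
weakly monotone across tools, which is what the ordering tests exploit. The
cohort is sampled once per seed and held fixed across PSA runs (parameters
and event draws are redrawn); whether to resample the cohort per run is a
configuration-level choice we deliberately fixed for variance reduction.
Everything derives from `numpy.random.SeedSequence`, so a seed reproduces
any output bit-identically.

## Economics

Full incremental analysis: sort by QALYs; drop strictly dominated
strategies; drop extendedly dominated ones by enforcing increasing ICERs
along the remaining sequence (equivalent to the lower convex hull, verified
against a brute-force blend search in the tests); ICERs between consecutive
frontier members. Exact ties in QALYs and costs are broken by input order;
equal-QALY ties keep the cheaper strategy. The MAICER decision takes the
most effective frontier member with ICER ≤ MAICER (boundary inclusive),
which equals the net-monetary-benefit argmax. The MTC tariff threshold
analysis re-costs simulated outcomes exactly — admission premiums enter the
ledger linearly and do not affect survival — so no re-simulation is needed.

The ISS 9–15 benefit scenario interpolates the local-care RRs linearly on
the RR scale, `RR(f) = 1 + f·(RR_full − 1)`: at f = 0.5 the 1-year RR is
1.32 and the 30-day RR 1.125. Note the published scenario table prints 1.07
for the 30-day RR at f = 0.25 where linear interpolation gives 1.0625
(log-linear would give 1.057); we implement the linear rule, which
reproduces every other printed cell (1.13, 1.19, 1.16, 1.32, 1.48), and
flag the 1.07 as a printed inconsistency.

## Problem sizes

Defaults follow the published stability assessment (25,000 patients, 2,000
PSA runs). The packaged tests and examples run scaled-down configurations
(e.g. 100 runs × 2,000 patients for the null-effect invariant, 60 × 5,000
for ordering checks, 100,000-patient single runs for flow/marginal
recovery), chosen so each check's Monte-Carlo error is small against the
effect it measures; the engine is vectorised, so a full-size PSA is
minutes-scale on one core.

## Known limitations

- Nine fixed sensitivity/specificity pairs; no modelling of *which* patients
  a real tool misclassifies (no correlation between tool error and
  survival-equation covariates), though the patient-level design is built to
  accept such a tool model later.
- No geography (MTC-catchment patients are out of scope by design), no
  direct-vs-transferred MTC benefit distinction, no comorbidity-adjusted
  survival variant beyond the pluggable logistic interface.
- Costs are taken as given in 2017/18 prices; no re-inflation machinery.
- The deterministic published frontier cannot be recovered from printed
  rounded values; validation of the frontier algorithm is therefore by
  oracle equivalence, not by reproducing that table's dominance labels.
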