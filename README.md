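# triagesim

A patient-level, probabilistic cost-utility model of prehospital major-trauma
triage in an English trauma system, for health-economics analysts and trauma
researchers who want to ask: *given the unavoidable trade-off between a triage
tool's sensitivity and specificity, which tool is cost-effective?*

## The decision problem

Paramedics use triage tools (plus judgement) to decide whether a patient with
suspected severe injury bypasses the local hospital for a major trauma centre
(MTC). Severely injured patients — Injury Severity Score (ISS) ≥ 16 — do
better at MTCs, but MTC care costs more, and every tool trades sensitivity
(severe patients correctly sent to an MTC) against specificity (less-injured
patients correctly kept local). `triagesim` compares nine empirically derived
sensitivity/specificity pairs, from (99.8%, 2.5%) down to (28.4%, 88.6%), on
one simulated population.

For each simulated patient the model chains:

1. **Triage and transfer** — tool-positive with probability *sens* (ISS ≥ 16)
   or 1 − *spec* (ISS < 16); secondary local→MTC transfer with category-
   specific probabilities (TP 26.6%, FN 32.5%, TN 4.3%, FP 7.4%).
2. **30-day survival** — logistic model
   `logit(Ps) = b0 + b_age·age + b_ISS·ISS + b_GCS·GCS + b_male·male`,
   with RR 1.25 on death for ISS ≥ 16 patients treated only locally.
3. **30 days → 1 year** — death probability 3.6% (ISS ≥ 16; ×1.64 if never at
   an MTC) or 1.7% (ISS < 16).
4. **Long term** — annual life-table walk with hazard ratios 5.19 (ISS ≥ 16)
   and 1.38 (ISS < 16): `q' = 1 − (1 − q)^HR`.
5. **QALYs and costs** — utility `u(age, sex) × 0.789` for ISS ≥ 9 survivors,
   banded acute treatment tariffs, MTC admission premiums (£2,819 / £1,466),
   transfer cost £252, £1,766 post-discharge, and age/sex NHS costs scaled by
   1.45 / 1.25 thereafter; everything beyond year 0 discounted at 3.5% p.a.

Strategies are then ranked by full incremental analysis: dominated and
extendedly dominated tools are removed, ICERs (ΔCost/ΔQALY) computed between
consecutive frontier members, and the cost-effective tool at a maximum
acceptable ICER (MAICER, £20,000–£30,000/QALY) identified — equivalently the
net-monetary-benefit maximiser. A probabilistic sensitivity analysis (PSA)
redraws every parameter from moment-matched distributions (Beta/Gamma/
Lognormal) each run and computes ICERs from mean costs and QALYs.

The original patient-level registry and the published survival-equation
coefficients are not redistributable, so the package ships a synthetic cohort
generator matched to the registry's printed marginals, an illustrative
"TARN-like" survival equation, and synthetic life-table/NHS-cost generators —
all replaceable via configuration. See `docs/methods.md`.

## Worked example

```python
from triagesim import (CohortSpec, default_parameters, incremental_analysis,
                       cost_effective_at, run_deterministic, sample_cohort)

params = default_parameters()
cohort = sample_cohort(100_000, CohortSpec(), seed=1)
frontier = incremental_analysis(run_deterministic(cohort, params, seed=2))
print(frontier.to_frame().round(3).to_string(index=False))
```

prints

```
              strategy  qalys     costs               status      icer
28.4% Sens, 88.6% Spec 13.999 40080.133           comparator       NaN
57.0% Sens, 80.0% Spec 14.008 40166.169          on-frontier  9888.124
64.2% Sens, 76.1% Spec 14.010 40189.143          on-frontier 10893.807
69.8% Sens, 70.1% Spec 14.012 40211.745 extendedly dominated       NaN
74.6% Sens, 65.7% Spec 14.013 40229.585 extendedly dominated       NaN
87.5% Sens, 62.8% Spec 14.017 40267.358          on-frontier 10918.676
90.4% Sens, 58.4% Spec 14.018 40280.478          on-frontier 13204.241
94.8% Sens, 18.7% Spec 14.019 40340.350 extendedly dominated       NaN
 99.8% Sens, 2.5% Spec 14.020 40372.983          on-frontier 42004.708
```

Reading it: mean discounted QALYs and costs per patient both rise with
sensitivity; several mid-range tools are extendedly dominated (a blend of
their neighbours buys the same QALYs cheaper); each frontier ICER is the
price of the next step up in sensitivity. Here
`cost_effective_at(frontier, 20_000)` and `...at(frontier, 30_000)` both pick
the 90.4%-sensitivity tool — with the illustrative survival coefficients and
synthetic cost schedules, absolute QALY/cost levels and hence ICERs differ
from analyses run against the restricted-access inputs; the structure
(orderings, dominance pattern, flow counts) is what carries over.

The `examples/` directory has one narrative script per capability (cohort
generation, analytic flows, deterministic run, PSA, scenarios), and the
`triagesim` CLI exposes the same workflow from a shell
(`triagesim psa --runs 200 --patients 5000 --seed 7 --out results/`).

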