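"""Patient-level simulation engine: deterministic runs and PSA.

One run pushes every cohort member through all nine triage strategies with
common random numbers: a single set of per-patient uniform draws (triage,
transfer, 30-day death, 1-year death) and one long-term death-age stream are
shared across tools, so strategies differ only through their decision
thresholds. This removes between-strategy Monte-Carlo noise from the
incremental comparisons, mirroring how the strategies would act on one and
the same population.

The PSA fixes the cohort for a given seed and redraws the parameter set
(and the patient-level event draws) each run; decision outputs are computed
from mean costs and mean QALYs across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import costs as costmod
from . import qaly as qalymod
from . import survival as survmod
from .cohort import CohortSpec, sample_cohort
from .costs import NhsCostSchedule
from .parameters import ParameterSet, TriageTool, draw_parameters
from .survival import LifeTable
from .triage import assign_pathway_vec, classify_vec

__all__ = ["StrategyOutcome", "PsaResult", "run_deterministic", "run_psa",
           "stability_check", "outcomes_frame"]


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-strategy mean outcomes over one simulated population."""

    label: str
    sensitivity: float
    specificity: float
    mtc_per_100k: float
    mtc_iss16_per_100k: float
    mtc_issLT16_per_100k: float
    p_death_30d: float
    p_death_30d_1yr: float
    mean_life_years: float
    mean_qalys: float
    mean_costs: float
    frac_evermtc_iss16: float    # per-patient fractions, used for exact
    frac_evermtc_iss9to15: float  # re-costing in tariff threshold analyses

    def __post_init__(self) -> None:
        if self.mean_qalys > self.mean_life_years + 1e-9:
            raise ValueError("QALYs cannot exceed life years")
        total = self.mtc_iss16_per_100k + self.mtc_issLT16_per_100k
        if abs(total - self.mtc_per_100k) > 1e-6:
            raise ValueError("MTC subgroup flows must sum to the total")


def outcomes_frame(outcomes: list[StrategyOutcome]) -> pd.DataFrame:
    """Tabulate outcomes with one row per strategy."""
    return pd.DataFrame([{f.name: getattr(o, f.name) for f in fields(o)}
                         for o in outcomes])


@dataclass(frozen=True)
class PsaResult:
    """Per-run outcomes and their across-run means."""

    runs: pd.DataFrame    # long format: run, label, one column per outcome
    means: pd.DataFrame   # one row per strategy, averaged over runs
    n_runs: int
    n_patients: int
    seed: int
    n_resampled_draws: int = 0

    def outcomes(self) -> list[StrategyOutcome]:
        return [StrategyOutcome(**{f.name: row[f.name]
                                   for f in fields(StrategyOutcome)})
                for _, row in self.means.iterrows()]


def _cohort_arrays(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "age": cohort["age"].to_numpy(dtype=float),
        "male": cohort["male"].to_numpy(dtype=int),
        "iss": cohort["iss"].to_numpy(dtype=int),
        "gcs": cohort["gcs"].to_numpy(dtype=float),
        "blunt": cohort["blunt"].to_numpy(dtype=bool),
    }


def _simulate_run(arrays: dict[str, np.ndarray], tools: tuple[TriageTool, ...],
                  params: ParameterSet, life_table: LifeTable,
                  schedule: NhsCostSchedule,
                  seed_seq: np.random.SeedSequence) -> pd.DataFrame:
    """All strategies over one cohort with one set of common random numbers."""
    n = arrays["age"].size
    age, male, iss = arrays["age"], arrays["male"], arrays["iss"]
    iss16 = iss >= 16
    iss9to15 = (iss >= 9) & ~iss16

    # purpose-split streams shared by every tool
    s_triage, s_transfer, s_30d, s_1yr, s_long = seed_seq.spawn(5)
    u_triage = np.random.default_rng(s_triage).random(n)
    u_transfer = np.random.default_rng(s_transfer).random(n)
    u_30d = np.random.default_rng(s_30d).random(n)
    u_1yr = np.random.default_rng(s_1yr).random(n)

    # tool-independent quantities
    rate = params.econ.discount_rate
    hr = np.where(iss16, params.effects.hr_longterm_iss16,
                  params.effects.hr_longterm_issLT16)
    K = survmod.simulate_death_years(age, male, hr, life_table,
                                     np.random.default_rng(s_long))
    q_surv, ly_surv = qalymod.lifetime_qalys_vec(age, male, iss, K, rate,
                                                 params.utility)
    c_long = costmod.longterm_costs_vec(age, male, iss16, K, rate, schedule,
                                        params.costs)
    u0 = qalymod.patient_utility(age, male, iss, params.utility)

    rows = []
    for tool in tools:
        pos = classify_vec(iss16, tool, u_triage)
        _, transferred, ever_mtc = assign_pathway_vec(pos, iss16,
                                                      params.transfer, u_transfer)
        p30 = survmod.p_death_30d(age, iss, arrays["gcs"], male, ever_mtc,
                                  params.effects, params.survival)
        died30 = u_30d < p30
        p1 = survmod.p_death_30d_to_1yr(iss, ever_mtc, params.effects)
        died1yr = ~died30 & (u_1yr < p1)
        survived = ~died30 & ~died1yr

        qalys = np.where(survived, q_surv, np.where(died1yr, 0.5 * u0, 0.0))
        life_years = np.where(survived, ly_surv, np.where(died1yr, 0.5, 0.0))
        treatment, transfer_cost = costmod.acute_cost_vec(
            iss, arrays["blunt"], ever_mtc, transferred, params.costs)
        total_cost = (treatment + transfer_cost
                      + np.where(died30, 0.0, params.costs.post_discharge_6mo)
                      + np.where(survived, c_long, 0.0))

        rows.append({
            "label": tool.label,
            "sensitivity": tool.sensitivity,
            "specificity": tool.specificity,
            "mtc_per_100k": ever_mtc.mean() * 1e5,
            "mtc_iss16_per_100k": (ever_mtc & iss16).mean() * 1e5,
            "mtc_issLT16_per_100k": (ever_mtc & ~iss16).mean() * 1e5,
            "p_death_30d": died30.mean(),
            "p_death_30d_1yr": died1yr.mean(),
            "mean_life_years": life_years.mean(),
            "mean_qalys": qalys.mean(),
            "mean_costs": total_cost.mean(),
            "frac_evermtc_iss16": (ever_mtc & iss16).mean(),
            "frac_evermtc_iss9to15": (ever_mtc & iss9to15).mean(),
        })
    return pd.DataFrame(rows)


def _to_outcomes(df: pd.DataFrame) -> list[StrategyOutcome]:
    return [StrategyOutcome(**{f.name: row[f.name]
                               for f in fields(StrategyOutcome)})
            for _, row in df.iterrows()]


def run_deterministic(cohort: pd.DataFrame, params: ParameterSet,
                      tools: tuple[TriageTool, ...] | None = None,
                      life_table: LifeTable | None = None,
                      schedule: NhsCostSchedule | None = None,
                      seed: int = 0) -> list[StrategyOutcome]:
    """One run with every parameter at its point estimate.

    Patient-level events remain stochastic (this is a microsimulation), but
    all parameters are deterministic and all strategies share the same
    patient-level draws.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    tools = tools or params.tools
    if not tools:
        raise ValueError("no triage tools given")
    life_table = life_table or LifeTable.gompertz_makeham(params.econ.horizon_age_cap)
    schedule = schedule or NhsCostSchedule.stylised(params.econ.horizon_age_cap)
    df = _simulate_run(_cohort_arrays(cohort), tuple(tools), params, life_table,
                       schedule, np.random.SeedSequence(seed))
    return _to_outcomes(df)


def run_psa(params: ParameterSet,
            cohort: pd.DataFrame | CohortSpec | None = None,
            tools: tuple[TriageTool, ...] | None = None,
            n_runs: int = 2000, n_patients: int = 25000, seed: int = 0,
            life_table: LifeTable | None = None,
            schedule: NhsCostSchedule | None = None) -> PsaResult:
    """Probabilistic sensitivity analysis.

    The cohort is sampled once per seed (or taken as given) and held fixed;
    each run redraws the parameter set from its uncertainty distributions and
    the patient-level event draws, then simulates every strategy with common
    random numbers. Defaults (25,000 patients, 2,000 runs) follow the
    stability assessment of the underlying analysis; scale both down for
    exploratory work.
    """
    if n_runs < 1 or n_patients < 1:
        raise ValueError("n_runs and n_patients must be >= 1")
    tools = tools or params.tools
    if not tools:
        raise ValueError("no triage tools given")
    root = np.random.SeedSequence(seed)
    s_cohort, s_params, s_events = root.spawn(3)
    if cohort is None or isinstance(cohort, CohortSpec):
        spec = cohort if isinstance(cohort, CohortSpec) else CohortSpec()
        cohort = sample_cohort(n_patients, spec,
                               np.random.default_rng(s_cohort))
    else:
        cohort = cohort.iloc[:n_patients] if len(cohort) > n_patients else cohort
    arrays = _cohort_arrays(cohort)
    life_table = life_table or LifeTable.gompertz_makeham(params.econ.horizon_age_cap)
    schedule = schedule or NhsCostSchedule.stylised(params.econ.horizon_age_cap)

    param_rng = np.random.default_rng(s_params)
    event_seqs = s_events.spawn(n_runs)
    frames = []
    for run in range(n_runs):
        drawn = draw_parameters(params, param_rng)
        df = _simulate_run(arrays, tuple(tools), drawn, life_table, schedule,
                           event_seqs[run])
        df.insert(0, "run", run)
        frames.append(df)
    runs = pd.concat(frames, ignore_index=True)
    numeric = [c for c in runs.columns if c not in ("run", "label")]
    means = runs.groupby("label", sort=False)[numeric].mean().reset_index()
    return PsaResult(runs=runs, means=means, n_runs=n_runs,
                     n_patients=len(cohort), seed=seed)


def stability_check(psa: PsaResult, outcome: str = "mean_qalys",
                    label: str | None = None, tol: float = 1e-3):
    """Running-mean stability of one PSA outcome.

    Returns ``(trace, converged)``: the cumulative mean over runs for the
    given strategy (default: the first), and whether the final 10% of runs
    moved that mean by less than ``tol``.
    """
    if psa.n_runs < 2:
        raise ValueError("need at least 2 runs")
    if label is None:
        label = psa.means["label"].iloc[0]
    series = (psa.runs[psa.runs["label"] == label]
              .sort_values("run")[outcome].to_numpy())
    trace = np.cumsum(series) / np.arange(1, series.size + 1)
    tail = max(1, int(np.ceil(0.10 * trace.size)))
    converged = bool(np.max(np.abs(trace[-tail:] - trace[-1])) < tol)
    return trace, converged
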