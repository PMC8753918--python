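"""Three-stage mortality model.

Stage 1 (0-30 days): a logistic probability-of-survival equation in age,
ISS, GCS and sex, with a relative risk of death applied to ISS >= 16
patients treated only at a local hospital. Stage 2 (30 days to 1 year):
fixed probabilities by severity group, again with a local-hospital relative
risk for ISS >= 16. Stage 3 (beyond 1 year): an annual Bernoulli walk over
a general-population life table, with long-term trauma hazard ratios applied
on the hazard scale, ``q' = 1 - (1 - q)^hr``.

The shipped life-table constructor is a synthetic Gompertz-Makeham
approximation to UK national life tables; real ONS tables can be loaded from
CSV (columns ``age,sex,qx`` with sex in {female, male} or {0, 1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import EffectParams, SurvivalModelSpec

__all__ = ["LifeTable", "p_survival_30d", "p_death_30d", "p_death_30d_to_1yr",
           "annual_death_prob", "simulate_death_age", "linear_predictor",
           "life_expectancy"]


class LifeTable:
    """Annual death probabilities q(age, sex) for ages 0..cap, with q(cap) = 1."""

    def __init__(self, q_female: np.ndarray, q_male: np.ndarray):
        q_female = np.asarray(q_female, dtype=float)
        q_male = np.asarray(q_male, dtype=float)
        if q_female.shape != q_male.shape or q_female.ndim != 1:
            raise ValueError("life table needs matching 1-d q arrays")
        for q in (q_female, q_male):
            if np.any((q < 0) | (q > 1)):
                raise ValueError("q outside [0, 1]")
            if q[-1] != 1.0:
                raise ValueError("q at the horizon cap must be 1")
        self._q = np.stack([q_female, q_male])  # [sex, age]
        self.max_age = q_female.size - 1

    @classmethod
    def gompertz_makeham(cls, max_age: int = 100, *,
                         makeham: tuple[float, float] = (2.5e-4, 1.5e-4),
                         gompertz_b: tuple[float, float] = (1.826e-5, 1.242e-5),
                         gompertz_c: float = 0.10) -> "LifeTable":
        """Synthetic UK-like life table from a Gompertz-Makeham hazard.

        mu(x) = A + B*exp(C*x), converted to annual probabilities by
        q(x) = 1 - exp(-integral of mu over [x, x+1]). Default parameters give
        period life expectancies at birth of roughly 79 (male) and 83
        (female), matching recent UK national tables to within about a year.
        Tuples are (male, female) ordered as (makeham A, gompertz B).
        """
        x = np.arange(max_age + 1, dtype=float)
        qs = []
        for (a, b) in ((makeham[1], gompertz_b[1]),   # female
                       (makeham[0], gompertz_b[0])):  # male
            cum = a + b * np.exp(gompertz_c * x) * (np.expm1(gompertz_c)) / gompertz_c
            q = -np.expm1(-cum)
            q[-1] = 1.0
            qs.append(np.clip(q, 0.0, 1.0))
        return cls(qs[0], qs[1])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        missing = {"age", "sex", "qx"} - set(df.columns)
        if missing:
            raise ValueError(f"life table CSV missing columns: {sorted(missing)}")
        sex = df["sex"].map({"female": 0, "male": 1, 0: 0, 1: 1})
        if sex.isna().any():
            raise ValueError("sex must be female/male or 0/1")
        qs = []
        for s in (0, 1):
            sub = df[sex == s].sort_values("age")
            ages = sub["age"].to_numpy()
            if not np.array_equal(ages, np.arange(ages.min(), ages.max() + 1)) \
                    or ages.min() != 0:
                raise ValueError("life table must cover all integer ages from 0")
            qs.append(sub["qx"].to_numpy(dtype=float))
        return cls(qs[0], qs[1])

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.max_age + 1)
        return pd.DataFrame({
            "age": np.tile(ages, 2),
            "sex": np.repeat(["female", "male"], ages.size),
            "qx": np.concatenate([self._q[0], self._q[1]]),
        })

    def q(self, age, male):
        """Annual death probability; ``age`` beyond the cap raises."""
        age_idx = np.asarray(age, dtype=int)
        if np.any(age_idx > self.max_age) or np.any(age_idx < 0):
            raise ValueError("age beyond life-table coverage")
        return self._q[np.asarray(male, dtype=int), age_idx]


def linear_predictor(age, iss, gcs, male, spec: SurvivalModelSpec):
    c = spec.coefficients
    return (c["intercept"] + c["age"] * np.asarray(age, dtype=float)
            + c["iss"] * np.asarray(iss, dtype=float)
            + c["gcs"] * np.asarray(gcs, dtype=float)
            + c["male"] * np.asarray(male, dtype=float))


def p_survival_30d(age, iss, gcs, male, spec: SurvivalModelSpec):
    """30-day probability of survival, inverse-logit of the linear predictor."""
    lp = linear_predictor(age, iss, gcs, male, spec)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-lp))
    return out


def p_death_30d(age, iss, gcs, male, ever_mtc, effects: EffectParams,
                spec: SurvivalModelSpec):
    """30-day death probability with the local-hospital relative risk applied.

    The RR of 1.25 applies to ISS >= 16 patients never treated at an MTC;
    ISS < 16 carries RR 1 by assumption, except in the ISS 9-15 benefit
    scenario where an interpolated RR applies to local-only care.
    """
    iss = np.asarray(iss)
    d = 1.0 - p_survival_30d(age, iss, gcs, male, spec)
    local = ~np.asarray(ever_mtc, dtype=bool)
    rr = np.ones_like(d)
    rr = np.where(local & (iss >= 16), effects.rr_death30_local_iss16, rr)
    rr = np.where(local & (iss >= 9) & (iss < 16),
                  effects.rr_death30_local_iss9to15, rr)
    rr = np.where(local & (iss < 9), effects.rr_death30_local_issLT16, rr)
    return np.minimum(1.0, d * rr)


def p_death_30d_to_1yr(iss, ever_mtc, effects: EffectParams):
    """Probability of death between 30 days and 1 year post-injury."""
    iss = np.asarray(iss)
    local = ~np.asarray(ever_mtc, dtype=bool)
    p = np.where(iss >= 16, effects.p_death_30d_1yr_iss16,
                 effects.p_death_30d_1yr_issLT16)
    rr = np.ones_like(p)
    rr = np.where(local & (iss >= 16), effects.rr_1yr_local_iss16, rr)
    rr = np.where(local & (iss >= 9) & (iss < 16),
                  effects.rr_1yr_local_iss9to15, rr)
    return np.minimum(1.0, p * rr)


def annual_death_prob(age, male, hr: float, table: LifeTable):
    """Life-table annual death probability under a proportional hazard.

    q' = 1 - (1 - q)^hr, clipped to [0, 1].
    """
    q = np.asarray(table.q(age, male), dtype=float)
    return np.clip(1.0 - np.power(1.0 - q, hr), 0.0, 1.0)


def simulate_death_years(age, male, hr, table: LifeTable,
                         rng: np.random.Generator) -> np.ndarray:
    """Years survived beyond 1 year post-injury, vectorised annual walk.

    For each patient (assumed alive 1 year post-injury) returns the cycle
    number K >= 1 at which death occurs; the patient dies during calendar
    year K after injury, at age ``floor(age) + K``. The walk is capped at the
    life-table horizon, where q = 1 guarantees termination.
    """
    age0 = np.asarray(np.floor(age), dtype=int)
    male = np.asarray(male, dtype=int)
    hr = np.broadcast_to(np.asarray(hr, dtype=float), age0.shape)
    n = age0.size
    death_year = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)
    t = 1
    while alive.any():
        a = np.minimum(age0[alive] + t, table.max_age)
        q = np.asarray(table.q(a, male[alive]), dtype=float)
        qh = np.clip(1.0 - np.power(1.0 - q, hr[alive]), 0.0, 1.0)
        dies = rng.random(alive.sum()) < qh
        idx = np.flatnonzero(alive)
        death_year[idx[dies]] = t
        alive[idx[dies]] = False
        t += 1
    return death_year


def simulate_death_age(age: float, male: int, hr: float, table: LifeTable,
                       rng: np.random.Generator) -> float:
    """Age at death for one patient who survived to 1 year post-injury."""
    k = simulate_death_years(np.array([age]), np.array([male]), hr, table, rng)
    return float(np.floor(age) + k[0])


def life_expectancy(age: int, male: int, table: LifeTable, hr: float = 1.0) -> float:
    """Curtate expected years remaining from ``age`` under the hazard ratio.

    Deterministic companion to :func:`simulate_death_years`: the expected
    death cycle E[K] = sum over t >= 0 of S(t), with S(t) the probability of
    surviving cycles 1..t.
    """
    total, surv, t = 0.0, 1.0, 1
    while surv > 0 and age + t <= table.max_age + 1:
        a = min(age + t, table.max_age)
        q = annual_death_prob(a, male, hr, table)
        total += surv  # survived cycles so far -> at risk in cycle t
        surv *= 1.0 - float(q)
        t += 1
    # E[K] = sum_{t>=1} t * P(K = t) = sum_{t>=0} P(K > t); K >= 1 always
    return total
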