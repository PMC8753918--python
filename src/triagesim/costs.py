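"""Cost accrual: acute treatment, transfers, post-discharge and lifetime costs.

Acute costs comprise an ISS-banded treatment cost (separate blunt and
penetrating tariffs), an MTC admission premium for patients who ever reach
an MTC (by ISS band; no premium below ISS 9), and a fixed cost per secondary
transfer. Thirty-day survivors incur a one-off discharge-to-6-months cost.
Beyond year one, survivors accrue age/sex-specific general-population NHS
costs scaled by a severity multiplier (1.45 for ISS >= 16, 1.25 below),
discounted annually with a half-year charge in the year of death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import CostParams, band_lookup

__all__ = ["CostLedger", "NhsCostSchedule", "acute_cost", "post_discharge_cost",
           "longterm_annual_cost", "lifetime_costs", "longterm_costs_vec",
           "acute_cost_vec"]


@dataclass(frozen=True)
class CostLedger:
    """Per-patient cost components (GBP); total reconciles to the sum."""

    acute: float
    transfer: float
    post_discharge: float
    longterm_discounted: float

    @property
    def total_discounted(self) -> float:
        return (self.acute + self.transfer + self.post_discharge
                + self.longterm_discounted)


class NhsCostSchedule:
    """Annual general-population NHS cost by (age band, sex)."""

    def __init__(self, bands: pd.DataFrame):
        required = {"age_lo", "age_hi", "sex", "annual_cost"}
        missing = required - set(bands.columns)
        if missing:
            raise ValueError(f"cost schedule missing columns: {sorted(missing)}")
        if (bands["annual_cost"] < 0).any():
            raise ValueError("annual costs must be non-negative")
        self._bands = bands.copy()
        sex = bands["sex"].map({"female": 0, "male": 1, 0: 0, 1: 1})
        self.max_age = int(bands["age_hi"].max())
        cost = np.full((2, self.max_age + 1), np.nan)
        for (_, row), s in zip(bands.iterrows(), sex):
            lo, hi = int(row["age_lo"]), int(row["age_hi"])
            cost[s, lo:hi + 1] = row["annual_cost"]
        if np.isnan(cost).any():
            raise ValueError("cost schedule has age gaps")
        self._cost = cost

    @classmethod
    def stylised(cls, max_age: int = 100) -> "NhsCostSchedule":
        """Synthetic age-increasing schedule (GBP/year), quadratic in age.

        A stylised stand-in for published English age/sex NHS cost curves:
        roughly 500 GBP/year for young adults rising to about 3,000 GBP/year
        at age 90, men slightly costlier at older ages.
        """
        ages = np.arange(max_age + 1)
        rows = []
        for sex, scale in (("female", 1.0), ("male", 1.05)):
            cost = scale * (350.0 + 3.0 * ages + 0.30 * ages ** 2)
            rows.append(pd.DataFrame({"age_lo": ages, "age_hi": ages,
                                      "sex": sex, "annual_cost": cost}))
        return cls(pd.concat(rows, ignore_index=True))

    @classmethod
    def from_csv(cls, path) -> "NhsCostSchedule":
        return cls(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return self._bands.copy()

    def annual_cost(self, age, male):
        age_idx = np.asarray(age, dtype=int)
        if np.any(age_idx > self.max_age) or np.any(age_idx < 0):
            raise ValueError("age beyond cost-schedule coverage")
        return self._cost[np.asarray(male, dtype=int), age_idx]


def acute_cost(iss: int, blunt: bool, ever_mtc: bool, transferred: bool,
               params: CostParams) -> float:
    """Acute-phase cost: banded treatment + MTC premium + transfer cost."""
    bands = (params.blunt_treatment_bands if blunt
             else params.penetrating_treatment_bands)
    cost = band_lookup(bands, iss)
    if ever_mtc:
        if iss >= 16:
            cost += params.mtc_admit_iss16
        elif iss >= 9:
            cost += params.mtc_admit_iss9to15
    if transferred:
        cost += params.transfer_cost
    return cost


def acute_cost_vec(iss, blunt, ever_mtc, transferred, params: CostParams):
    """Vectorised :func:`acute_cost`; treatment and premium split out.

    Returns ``(treatment + premium, transfer)`` arrays so the transfer
    component can be ledgered separately.
    """
    iss = np.asarray(iss)
    blunt = np.asarray(blunt, dtype=bool)
    ever_mtc = np.asarray(ever_mtc, dtype=bool)

    def banded(bands):
        uppers = [u for u, _ in bands[:-1]]
        costs = np.array([c for _, c in bands])
        return costs[np.searchsorted(np.array(uppers), iss, side="left")]

    treatment = np.where(blunt, banded(params.blunt_treatment_bands),
                         banded(params.penetrating_treatment_bands)).astype(float)
    premium = np.where(iss >= 16, params.mtc_admit_iss16,
                       np.where(iss >= 9, params.mtc_admit_iss9to15, 0.0))
    treatment += np.where(ever_mtc, premium, 0.0)
    transfer = np.where(np.asarray(transferred, dtype=bool),
                        params.transfer_cost, 0.0)
    return treatment, transfer


def post_discharge_cost(survived_30d: bool, params: CostParams) -> float:
    """One-off discharge-to-6-months cost, charged to all 30-day survivors."""
    return params.post_discharge_6mo if survived_30d else 0.0


def longterm_annual_cost(age, male, iss_ge16, schedule: NhsCostSchedule,
                         params: CostParams):
    """Annual long-term NHS cost: schedule value times the severity multiplier."""
    mult = np.where(np.asarray(iss_ge16, dtype=bool),
                    params.longterm_mult_iss16, params.longterm_mult_issLT16)
    return schedule.annual_cost(age, male) * mult


def longterm_costs_vec(age, male, iss_ge16, years_survived, rate: float,
                       schedule: NhsCostSchedule, params: CostParams):
    """Discounted long-term costs for year-1 survivors.

    Annual charges from year t = 1 to the death year K (half charge at t = K),
    discounted at (1 + r)^-t. Year 0 carries no long-term charge: the first
    six months fall under the acute and post-discharge costs.
    """
    age = np.asarray(np.floor(age), dtype=int)
    K = np.asarray(years_survived, dtype=int)
    if np.any(K < 1):
        raise ValueError("years_survived must be >= 1 for year-1 survivors")
    mult = np.where(np.asarray(iss_ge16, dtype=bool),
                    params.longterm_mult_iss16, params.longterm_mult_issLT16)
    total = np.zeros(age.shape, dtype=float)
    for t in range(1, int(K.max()) + 1):
        weight = np.where(t < K, 1.0, np.where(t == K, 0.5, 0.0))
        if not weight.any():
            continue
        a = np.minimum(age + t, schedule.max_age)
        total += weight * schedule.annual_cost(a, male) * mult / (1.0 + rate) ** t
    return total


def lifetime_costs(iss: int, blunt: bool, male: int, age: float,
                   ever_mtc: bool, transferred: bool,
                   died_30d: bool, died_30d_to_1yr: bool,
                   years_survived: int | None, rate: float,
                   schedule: NhsCostSchedule, params: CostParams) -> CostLedger:
    """Full per-patient cost ledger for one simulated outcome."""
    treatment, transfer = acute_cost_vec(
        np.array([iss]), np.array([blunt]), np.array([ever_mtc]),
        np.array([transferred]), params)
    post = post_discharge_cost(not died_30d, params)
    if died_30d or died_30d_to_1yr or years_survived is None:
        longterm = 0.0
    else:
        longterm = float(longterm_costs_vec(
            np.array([age]), np.array([male]), np.array([iss >= 16]),
            np.array([years_survived]), rate, schedule, params)[0])
    return CostLedger(acute=float(treatment[0]), transfer=float(transfer[0]),
                      post_discharge=post, longterm_discounted=longterm)
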