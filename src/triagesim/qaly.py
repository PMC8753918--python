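"""Utilities and discounted quality-adjusted life years (QALYs).

General-population utility follows a quadratic age regression with a male
offset; injured patients with ISS >= 9 carry a multiplicative utility
decrement derived from 1-year post-injury EQ-5D data (multiplier
u_injured / u_genpop at the source study's age/sex mix), while ISS < 9 is
assumed to leave long-term utility unaffected.

Accrual conventions: annual cycles from the injury year (t = 0,
undiscounted), discounting at (1 + r)^-t, a half-year utility credit in the
year of death; patients dying within 30 days accrue nothing, deaths between
30 days and 1 year accrue half a year.
"""

from __future__ import annotations

import numpy as np

from .parameters import UtilityParams

__all__ = ["gen_pop_utility", "utility_multiplier", "iss_multiplier",
           "patient_utility", "discounted_qalys", "lifetime_qalys_vec"]


def gen_pop_utility(age, male, params: UtilityParams):
    """General-population utility c + b1*age + b2*age^2 + b3*male, clipped to [0, 1].

    ``male`` may be binary or a proportion (population-average utility).
    """
    age = np.asarray(age, dtype=float)
    u = (params.ara_constant + params.ara_age * age
         + params.ara_age2 * age ** 2
         + params.ara_male * np.asarray(male, dtype=float))
    return np.clip(u, 0.0, 1.0)


def utility_multiplier(u_group: float, u_ref: float) -> float:
    """Multiplier applied to general-population utility: u_group / u_ref."""
    if u_ref <= 0:
        raise ValueError("reference utility must be positive")
    return u_group / u_ref


def iss_multiplier(iss, params: UtilityParams):
    """Per-patient utility multiplier: injured ratio for ISS >= 9, else 1.

    The ratio is the cohort utility (default 0.65) over the age/sex-matched
    general-population utility at the source study's demographics (0.824 for
    age 61, 59.1% male), i.e. 0.789 with the default inputs.
    """
    ref = float(gen_pop_utility(params.ref_age, params.ref_male_prop, params))
    mult = utility_multiplier(params.u_iss9plus, ref)
    return np.where(np.asarray(iss) >= 9, mult, 1.0)


def patient_utility(age, male, iss, params: UtilityParams):
    """Utility of an injured patient at a given age."""
    return np.clip(gen_pop_utility(age, male, params) * iss_multiplier(iss, params),
                   0.0, 1.0)


def lifetime_qalys_vec(age, male, iss, years_survived, rate: float,
                       params: UtilityParams):
    """Discounted QALYs and undiscounted life years for year-1 survivors.

    ``years_survived`` is the death cycle K >= 1: full utility credit in years
    t = 0..K-1 and a half-year credit in the death year t = K; life years are
    K + 0.5. Utility is re-evaluated each year at the patient's attained age.
    """
    age = np.asarray(age, dtype=float)
    K = np.asarray(years_survived, dtype=int)
    if np.any(K < 1):
        raise ValueError("years_survived must be >= 1 for year-1 survivors")
    qalys = np.zeros_like(age)
    mult = iss_multiplier(iss, params)
    for t in range(int(K.max()) + 1):
        weight = np.where(t < K, 1.0, np.where(t == K, 0.5, 0.0))
        if not weight.any():
            continue
        u = np.clip(gen_pop_utility(age + t, male, params) * mult, 0.0, 1.0)
        qalys += weight * u / (1.0 + rate) ** t
    return qalys, K + 0.5


def discounted_qalys(start_age: float, death_age: float, male: int, iss: int,
                     rate: float, params: UtilityParams):
    """Scalar wrapper of :func:`lifetime_qalys_vec` for one patient.

    Returns ``(discounted QALYs, undiscounted life years)``.
    """
    if death_age < start_age + 1:
        raise ValueError("death age must be at least one year after injury")
    K = int(round(death_age - start_age))
    q, ly = lifetime_qalys_vec(np.array([start_age]), np.array([male]),
                               np.array([iss]), np.array([K]), rate, params)
    return float(q[0]), float(ly[0])
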