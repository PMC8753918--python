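"""Synthetic trauma cohort generator.

The original patient-level cohort behind the model (a Dutch prehospital
triage study) is not redistributable, so the simulation is populated with a
synthetic cohort that reproduces its published marginal structure: age
46.8 +/- 21.3, 58.3% male, ISS 5.2 +/- 7.2 with 9.1% at ISS >= 16, GCS
14.4 +/- 1.9, 98.2% blunt trauma.

Marginals are calibrated exactly by moment matching:

- age: truncated normal on [age_min, age_max], parent mean/sd solved so the
  truncated moments hit the targets;
- ISS: discrete mixture on 1..75 — a two-parameter exponential-family pmf
  ``exp(a*k + b*k^2)`` on 1..15 plus a geometric tail on 16..75 carrying
  exactly ``p_iss16`` mass, with (a, b, tail decay) solved so the overall
  mean/sd match;
- GCS: point mass at 15 plus a discretised-normal low tail on 3..14, with
  (weight, tail centre) solved for the target mean/sd.

Dependence (age, ISS, GCS) comes from a Gaussian copula with configurable
latent correlations; by default ISS and GCS are negatively correlated (more
severe anatomical injury tends to depress consciousness) and ISS is mildly
positively correlated with age. Sex and trauma type are independent
Bernoulli draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["CohortSpec", "sample_cohort", "summarize_cohort",
           "write_cohort_csv", "read_cohort_csv", "COHORT_COLUMNS"]

COHORT_COLUMNS = ("age", "male", "iss", "gcs", "blunt")

ISS_MAX = 75
GCS_MIN, GCS_MAX = 3, 15


class InfeasibleSpecWarning(UserWarning):
    """Marginal targets could not be matched exactly; best fit used instead."""


@dataclass(frozen=True)
class CohortSpec:
    """Target marginal moments and dependence structure of the cohort."""

    age_mean: float = 46.8
    age_sd: float = 21.3
    age_min: float = 16.0
    age_max: float = 100.0
    p_male: float = 0.583
    iss_mean: float = 5.2
    iss_sd: float = 7.2
    p_iss16: float = 0.091
    gcs_mean: float = 14.4
    gcs_sd: float = 1.9
    p_blunt: float = 0.982
    # latent Gaussian-copula correlations
    corr_age_iss: float = 0.10
    corr_iss_gcs: float = -0.40
    corr_age_gcs: float = 0.0
    gcs_tail_sd: float = 3.0  # spread of the low-GCS component

    def __post_init__(self) -> None:
        for name in ("p_male", "p_iss16", "p_blunt"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.age_sd <= 0 or self.iss_sd <= 0 or self.gcs_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be below age_max")
        for name in ("corr_age_iss", "corr_iss_gcs", "corr_age_gcs"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in (-1, 1)")

    # -- calibrated marginals (cached, deterministic) --------------------

    @cached_property
    def _age_parent(self) -> tuple[float, float]:
        """Parent (mu, sigma) whose [age_min, age_max] truncation matches targets."""
        lo, hi = self.age_min, self.age_max

        def resid(x):
            mu, log_sigma = x
            sigma = np.exp(log_sigma)
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
            return [m - self.age_mean, np.sqrt(v) - self.age_sd]

        sol = optimize.root(resid, [self.age_mean, np.log(self.age_sd)])
        if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
            warnings.warn("age targets not matched exactly; using best fit",
                          InfeasibleSpecWarning)
        mu, log_sigma = sol.x
        return float(mu), float(np.exp(log_sigma))

    @cached_property
    def iss_pmf(self) -> np.ndarray:
        """Calibrated pmf over ISS 1..75 (index 0 -> ISS 1)."""
        k_low = np.arange(1, 16, dtype=float)
        k_tail = np.arange(16, ISS_MAX + 1, dtype=float)
        target_m2 = self.iss_sd ** 2 + self.iss_mean ** 2

        def build(x):
            a, b, log_c = x
            low = np.exp(a * k_low + b * k_low ** 2)
            low *= (1.0 - self.p_iss16) / low.sum()
            tail = np.exp(-np.exp(log_c) * (k_tail - 16.0))
            tail *= self.p_iss16 / tail.sum()
            return np.concatenate([low, tail])

        k = np.arange(1, ISS_MAX + 1, dtype=float)

        def resid(x):
            pmf = build(x)
            m = pmf @ k
            m2 = pmf @ k ** 2
            # third equation pins the tail decay via its conditional mean
            if self.p_iss16 > 0:
                tail_mean = (pmf[15:] @ k[15:]) / self.p_iss16
            else:
                tail_mean = 24.0
            return [m - self.iss_mean, m2 - target_m2, tail_mean - 24.0]

        if self.p_iss16 == 0.0:
            # degenerate: no tail; solve the low component only
            def resid2(x):
                pmf = build([x[0], x[1], 0.0])
                return [pmf @ k - self.iss_mean, pmf @ k ** 2 - target_m2]
            sol = optimize.root(resid2, [-0.4, 0.01])
            ok = sol.success and np.max(np.abs(sol.fun)) < 1e-8
            pmf = build([sol.x[0], sol.x[1], 0.0])
        else:
            sol = optimize.root(resid, [-0.4, 0.01, np.log(0.125)])
            ok = sol.success and np.max(np.abs(sol.fun)) < 1e-8
            if not ok:  # relax the tail-shape condition, keep the moments
                sol = optimize.least_squares(resid, sol.x)
                ok = np.max(np.abs(sol.fun[:2])) < 1e-6
            pmf = build(sol.x)
        if not ok:
            warnings.warn("ISS targets not matched exactly; using best fit",
                          InfeasibleSpecWarning)
        return pmf

    @cached_property
    def gcs_pmf(self) -> np.ndarray:
        """Calibrated pmf over GCS 3..15 (index 0 -> GCS 3)."""
        k_low = np.arange(GCS_MIN, GCS_MAX, dtype=float)  # 3..14
        k = np.arange(GCS_MIN, GCS_MAX + 1, dtype=float)
        target_m2 = self.gcs_sd ** 2 + self.gcs_mean ** 2

        def build(x):
            logit_w, mu = x
            w = 1.0 / (1.0 + np.exp(-logit_w))
            tail = np.exp(-0.5 * ((k_low - mu) / self.gcs_tail_sd) ** 2)
            tail *= (1.0 - w) / tail.sum()
            return np.concatenate([tail, [w]])

        def resid(x):
            pmf = build(x)
            return [pmf @ k - self.gcs_mean, pmf @ k ** 2 - target_m2]

        sol = optimize.root(resid, [2.3, 8.0])
        ok = sol.success and np.max(np.abs(sol.fun)) < 1e-8
        if not ok:
            sol = optimize.least_squares(resid, sol.x)
            ok = np.max(np.abs(sol.fun)) < 1e-6
        if not ok:
            warnings.warn("GCS targets not matched exactly; using best fit",
                          InfeasibleSpecWarning)
        return build(sol.x)

    @cached_property
    def _copula_cholesky(self) -> np.ndarray:
        corr = np.array([
            [1.0, self.corr_age_iss, self.corr_age_gcs],
            [self.corr_age_iss, 1.0, self.corr_iss_gcs],
            [self.corr_age_gcs, self.corr_iss_gcs, 1.0],
        ])
        try:
            return np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ValueError("copula correlation matrix is not positive definite")


def _discrete_ppf(u: np.ndarray, pmf: np.ndarray, first_value: int) -> np.ndarray:
    cdf = np.cumsum(pmf)
    cdf[-1] = 1.0  # guard rounding
    return first_value + np.searchsorted(cdf, u, side="left")


def sample_cohort(n: int, spec: CohortSpec | None = None,
                  seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Sample ``n`` synthetic patients; bit-identical for a given seed.

    Returns a DataFrame with columns ``age`` (float years), ``male``,
    ``blunt`` (0/1), ``iss`` (int 1..75) and ``gcs`` (int 3..15).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or CohortSpec()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    z = rng.standard_normal((n, 3)) @ spec._copula_cholesky.T
    u = stats.norm.cdf(z)
    # clip away exact 0/1 from floating-point tails
    u = np.clip(u, 1e-12, 1.0 - 1e-12)

    mu, sigma = spec._age_parent
    a, b = (spec.age_min - mu) / sigma, (spec.age_max - mu) / sigma
    age = stats.truncnorm.ppf(u[:, 0], a, b, loc=mu, scale=sigma)
    iss = _discrete_ppf(u[:, 1], spec.iss_pmf, 1)
    # negative ISS-GCS latent correlation maps high ISS onto low GCS
    gcs = _discrete_ppf(u[:, 2], spec.gcs_pmf, GCS_MIN)
    male = (rng.random(n) < spec.p_male).astype(np.int8)
    blunt = (rng.random(n) < spec.p_blunt).astype(np.int8)
    return pd.DataFrame({"age": age, "male": male, "iss": iss.astype(np.int16),
                         "gcs": gcs.astype(np.int8), "blunt": blunt})


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Moment table in the layout of the published cohort summary."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    c = cohort
    rows = [
        ("Age", c["age"].mean(), c["age"].std(ddof=1)),
        ("Percentage Male", c["male"].mean(), np.nan),
        ("ISS", c["iss"].mean(), c["iss"].std(ddof=1)),
        ("Percentage with an ISS >= 16", (c["iss"] >= 16).mean(), np.nan),
        ("GCS", c["gcs"].mean(), c["gcs"].std(ddof=1)),
        ("Percentage with blunt trauma", c["blunt"].mean(), np.nan),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "mean", "sd"])


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return cohort.loc[:, list(COHORT_COLUMNS)]
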