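"""Moment-matched uncertainty distributions for probabilistic sensitivity analysis.

Each model parameter carries a :class:`DistributionSpec` describing its
uncertainty. Specs are constructed so that the analytic mean of the
distribution equals the deterministic point estimate exactly (moment
matching), which keeps the deterministic analysis and the centre of the PSA
consistent with each other.

Conventions follow standard health-economics practice: probabilities and
utilities are Beta, costs are Gamma, relative risks and hazard ratios are
Lognormal. A ``fixed`` family is available for parameters excluded from the
PSA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

FAMILIES = ("beta", "gamma", "lognormal", "dirichlet", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """A parametric uncertainty distribution for one model parameter.

    Parameters
    ----------
    family
        One of ``beta``, ``gamma``, ``lognormal``, ``dirichlet``, ``fixed``.
    params
        Family-specific parameters:

        - beta: ``a``, ``b`` (both > 0)
        - gamma: ``shape``, ``scale`` (both > 0)
        - lognormal: ``mu``, ``sigma`` (sigma >= 0), on the log scale
        - dirichlet: ``alpha`` (sequence of positives)
        - fixed: ``value``
    """

    family: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "beta":
            if not (p["a"] > 0 and p["b"] > 0):
                raise ValueError("beta requires a, b > 0")
        elif self.family == "gamma":
            if not (p["shape"] > 0 and p["scale"] > 0):
                raise ValueError("gamma requires shape, scale > 0")
        elif self.family == "lognormal":
            if not p["sigma"] >= 0:
                raise ValueError("lognormal requires sigma >= 0")
        elif self.family == "dirichlet":
            alpha = np.asarray(p["alpha"], dtype=float)
            if alpha.ndim != 1 or np.any(alpha <= 0):
                raise ValueError("dirichlet requires a 1-d positive alpha")
        elif self.family == "fixed":
            if "value" not in p:
                raise ValueError("fixed requires a value")

    @property
    def mean(self):
        """Analytic mean; equals the deterministic point estimate by construction."""
        p = self.params
        if self.family == "beta":
            return p["a"] / (p["a"] + p["b"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "lognormal":
            return math.exp(p["mu"] + 0.5 * p["sigma"] ** 2)
        if self.family == "dirichlet":
            alpha = np.asarray(p["alpha"], dtype=float)
            return alpha / alpha.sum()
        return p["value"]

    def draw(self, rng: np.random.Generator):
        """Sample one realisation."""
        p = self.params
        if self.family == "beta":
            return float(rng.beta(p["a"], p["b"]))
        if self.family == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        if self.family == "lognormal":
            return float(rng.lognormal(p["mu"], p["sigma"]))
        if self.family == "dirichlet":
            return rng.dirichlet(np.asarray(p["alpha"], dtype=float))
        return p["value"]

    # -- moment-matched constructors -------------------------------------

    @staticmethod
    def for_probability(mean: float, se: float | None = None,
                        ess: float | None = None) -> "DistributionSpec":
        """Beta spec with the given mean.

        Either an effective sample size ``ess`` (a = mean*ess, b = (1-mean)*ess)
        or a standard error ``se`` may be given. An SE incompatible with a Beta
        (se^2 >= mean*(1-mean)) is shrunk to half the maximum admissible SD,
        keeping the mean exact.
        """
        if not 0.0 <= mean <= 1.0:
            raise ValueError("probability mean outside [0, 1]")
        if mean in (0.0, 1.0) or se == 0:
            return DistributionSpec("fixed", {"value": mean})
        if ess is not None:
            return DistributionSpec("beta", {"a": mean * ess, "b": (1.0 - mean) * ess})
        if se is None:
            raise ValueError("give se or ess")
        max_var = mean * (1.0 - mean)
        var = min(se * se, 0.25 * max_var)
        nu = max_var / var - 1.0
        return DistributionSpec("beta", {"a": mean * nu, "b": (1.0 - mean) * nu})

    @staticmethod
    def for_cost(mean: float, se: float) -> "DistributionSpec":
        """Gamma spec with the given mean and SE (fixed at 0 for a zero cost)."""
        if mean < 0:
            raise ValueError("cost mean must be non-negative")
        if mean == 0 or se == 0:
            return DistributionSpec("fixed", {"value": mean})
        return DistributionSpec("gamma", {"shape": (mean / se) ** 2,
                                          "scale": se * se / mean})

    @staticmethod
    def for_ratio(mean: float, se: float) -> "DistributionSpec":
        """Lognormal spec (for RR/HR) with the given arithmetic mean and SE."""
        if mean <= 0:
            raise ValueError("ratio mean must be positive")
        if se == 0:
            return DistributionSpec("fixed", {"value": mean})
        sigma2 = math.log1p((se / mean) ** 2)
        return DistributionSpec("lognormal", {"mu": math.log(mean) - 0.5 * sigma2,
                                              "sigma": math.sqrt(sigma2)})

    @staticmethod
    def fixed(value: float) -> "DistributionSpec":
        return DistributionSpec("fixed", {"value": value})
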