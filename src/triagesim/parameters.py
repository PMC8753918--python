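"""Model parameters: point estimates, validation, configuration I/O and PSA draws.

The parameter set bundles every quantity the simulation needs — secondary
transfer probabilities, major-trauma-centre (MTC) effect sizes, utility and
cost inputs, economic settings, the 30-day survival-equation coefficients and
the nine triage tools under comparison. A default YAML file ships with the
package; any subset of it can be overridden from a user file.

Probabilistic sensitivity analysis (PSA) draws are produced by
:func:`draw_parameters`, which samples every uncertain parameter from a
moment-matched distribution (see :mod:`triagesim.distributions`) so the PSA
is centred on the deterministic point estimates.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .distributions import DistributionSpec

__all__ = [
    "TriageTool", "TransferProbs", "EffectParams", "UtilityParams",
    "CostParams", "EconSettings", "SurvivalModelSpec", "PsaSettings",
    "ParameterSet", "load_parameters", "save_parameters", "default_parameters",
    "interpolated_rr", "draw_parameters", "psa_distributions",
]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class TriageTool:
    """One triage strategy: the final scene decision, tool plus paramedic judgement.

    ``sensitivity`` is the probability that an ISS >= 16 patient is sent
    directly to an MTC; ``specificity`` the probability that an ISS < 16
    patient is sent to a local hospital.
    """

    label: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        _check_prob(f"{self.label} sensitivity", self.sensitivity)
        _check_prob(f"{self.label} specificity", self.specificity)


@dataclass(frozen=True)
class TransferProbs:
    """Probability of a secondary transfer (local hospital -> MTC) by triage category."""

    tp: float = 0.266  # ISS >= 16, tool positive (stabilised locally first)
    fn: float = 0.325  # ISS >= 16, tool negative
    tn: float = 0.043  # ISS < 16, tool negative
    fp: float = 0.074  # ISS < 16, tool positive

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            _check_prob(f"transfer.{name}", getattr(self, name))


@dataclass(frozen=True)
class EffectParams:
    """MTC effect sizes and fixed event probabilities of the survival cascade.

    Relative risks apply to patients treated only at a local hospital; care at
    an MTC at any point confers the full benefit. The ISS 9-15 relative risks
    default to 1 (no benefit) and are raised in the benefit-interpolation
    scenario via :func:`interpolated_rr`.
    """

    rr_death30_local_iss16: float = 1.25
    rr_death30_local_issLT16: float = 1.0
    p_death_30d_1yr_iss16: float = 0.036
    rr_1yr_local_iss16: float = 1.64
    p_death_30d_1yr_issLT16: float = 0.017
    hr_longterm_issLT16: float = 1.38
    hr_longterm_iss16: float = 5.19
    benefit_fraction_9to15: float = 0.0
    rr_death30_local_iss9to15: float = 1.0
    rr_1yr_local_iss9to15: float = 1.0

    def __post_init__(self) -> None:
        _check_prob("p_death_30d_1yr_iss16", self.p_death_30d_1yr_iss16)
        _check_prob("p_death_30d_1yr_issLT16", self.p_death_30d_1yr_issLT16)
        _check_prob("benefit_fraction_9to15", self.benefit_fraction_9to15)
        for name in ("rr_death30_local_iss16", "rr_death30_local_issLT16",
                     "rr_1yr_local_iss16", "hr_longterm_issLT16",
                     "hr_longterm_iss16", "rr_death30_local_iss9to15",
                     "rr_1yr_local_iss9to15"):
            _check_nonneg(name, getattr(self, name))


@dataclass(frozen=True)
class UtilityParams:
    """Utility inputs: injured-cohort utility and the general-population regression.

    The general-population EQ-5D utility is a quadratic in age with a male
    offset (Ara–Brazier form). ``u_iss9plus`` is the 1-year post-injury
    utility observed in an English MTC cohort with ISS >= 9; it is converted
    into a multiplier against the age/sex-matched general-population utility
    at the source study's demographics (``ref_age``, ``ref_male_prop``).
    """

    u_iss9plus: float = 0.65
    ara_constant: float = 0.9508566
    ara_age: float = -0.0002587
    ara_age2: float = -0.0000332
    ara_male: float = 0.0212126
    ref_age: float = 61.0
    ref_male_prop: float = 0.591

    def __post_init__(self) -> None:
        _check_prob("u_iss9plus", self.u_iss9plus)
        _check_prob("ref_male_prop", self.ref_male_prop)
        _check_nonneg("ref_age", self.ref_age)


BandMap = tuple[tuple[float | None, float], ...]


def _check_bands(name: str, bands: BandMap) -> None:
    if not bands:
        raise ValueError(f"{name}: empty band map")
    uppers = [b[0] for b in bands]
    if uppers[-1] is not None:
        raise ValueError(f"{name}: last band must be open-ended (upper null)")
    finite = [u for u in uppers[:-1]]
    if any(u is None for u in finite):
        raise ValueError(f"{name}: only the last band may be open-ended")
    if any(b <= a for a, b in zip(finite, finite[1:])):
        raise ValueError(f"{name}: band upper edges must be strictly increasing")
    for _, cost in bands:
        _check_nonneg(f"{name} cost", cost)


def band_lookup(bands: BandMap, iss: float) -> float:
    """Cost for an ISS from a band map of (inclusive upper edge, cost) pairs."""
    for upper, cost in bands:
        if upper is None or iss <= upper:
            return cost
    raise ValueError(f"ISS {iss} outside band coverage")  # pragma: no cover


@dataclass(frozen=True)
class CostParams:
    """Acute, transfer, post-discharge and long-term cost inputs (GBP, 2017/18).

    Treatment band edges are taken literally from the source tariffs,
    including the differing blunt (9 < ISS <= 16) and penetrating
    (9 < ISS <= 15) second-band edges; each band is (inclusive upper edge,
    cost), the last open-ended.
    """

    transfer_cost: float = 252.0
    mtc_admit_iss16: float = 2819.0
    mtc_admit_iss9to15: float = 1466.0
    blunt_treatment_bands: BandMap = (
        (9, 6198.0), (16, 8989.0), (25, 14205.0), (None, 21173.0))
    penetrating_treatment_bands: BandMap = (
        (9, 6501.0), (15, 6035.0), (24, 9453.0), (34, 12347.0), (None, 16438.0))
    post_discharge_6mo: float = 1766.0
    longterm_mult_iss16: float = 1.45
    longterm_mult_issLT16: float = 1.25

    def __post_init__(self) -> None:
        for name in ("transfer_cost", "mtc_admit_iss16", "mtc_admit_iss9to15",
                     "post_discharge_6mo", "longterm_mult_iss16",
                     "longterm_mult_issLT16"):
            _check_nonneg(name, getattr(self, name))
        _check_bands("blunt_treatment_bands", self.blunt_treatment_bands)
        _check_bands("penetrating_treatment_bands", self.penetrating_treatment_bands)


@dataclass(frozen=True)
class EconSettings:
    discount_rate: float = 0.035
    maicers: tuple[float, ...] = (20000.0, 30000.0)
    horizon_age_cap: int = 100

    def __post_init__(self) -> None:
        _check_nonneg("discount_rate", self.discount_rate)
        if any(m <= 0 for m in self.maicers):
            raise ValueError("maicers must be positive")
        if self.horizon_age_cap <= 0:
            raise ValueError("horizon_age_cap must be positive")


@dataclass(frozen=True)
class SurvivalModelSpec:
    """Pluggable 30-day probability-of-survival model.

    The default ``logit_linear`` form is
    ``logit(Ps) = b0 + b_age*age + b_iss*ISS + b_gcs*GCS + b_male*male``.
    The shipped coefficients are illustrative, TARN-like values (the published
    TARN coefficients are not redistributed here); users with access to the
    TARN publication can supply the real ones via configuration.
    """

    form: str = "logit_linear"
    coefficients: Mapping[str, float] = field(default_factory=lambda: {
        "intercept": 1.70, "age": -0.035, "iss": -0.085,
        "gcs": 0.30, "male": -0.10})

    _REQUIRED = ("intercept", "age", "iss", "gcs", "male")

    def __post_init__(self) -> None:
        if self.form != "logit_linear":
            raise ValueError(f"unknown survival model form {self.form!r}")
        missing = [k for k in self._REQUIRED if k not in self.coefficients]
        if missing:
            raise ValueError(f"survival model missing coefficients: {missing}")
        unknown = [k for k in self.coefficients if k not in self._REQUIRED]
        if unknown:
            raise ValueError(f"survival model has unknown coefficients: {unknown}")


@dataclass(frozen=True)
class PsaSettings:
    """How PSA distributions are built when not explicitly overridden.

    ``default_se_frac`` sets each parameter's SE to that fraction of its mean;
    tool sensitivities/specificities use Beta distributions with the given
    effective sample sizes (scale of the tool-derivation cohort).
    """

    default_se_frac: float = 0.20
    tool_ess_positive: float = 1000.0
    tool_ess_negative: float = 10000.0

    def __post_init__(self) -> None:
        _check_nonneg("default_se_frac", self.default_se_frac)
        if self.tool_ess_positive <= 0 or self.tool_ess_negative <= 0:
            raise ValueError("tool effective sample sizes must be positive")


@dataclass(frozen=True)
class ParameterSet:
    """Every model input needed for one deterministic or PSA evaluation."""

    transfer: TransferProbs = field(default_factory=TransferProbs)
    effects: EffectParams = field(default_factory=EffectParams)
    utility: UtilityParams = field(default_factory=UtilityParams)
    costs: CostParams = field(default_factory=CostParams)
    econ: EconSettings = field(default_factory=EconSettings)
    survival: SurvivalModelSpec = field(default_factory=SurvivalModelSpec)
    tools: tuple[TriageTool, ...] = ()
    psa: PsaSettings = field(default_factory=PsaSettings)


def interpolated_rr(rr_full: float, benefit_fraction: float) -> float:
    """Relative risk when only a fraction of the full MTC benefit applies.

    Linear on the RR scale: ``1 + f * (rr_full - 1)``, so f=0 gives no
    excess local-hospital risk and f=1 the full published RR.
    """
    if not 0.0 <= benefit_fraction <= 1.0:
        raise ValueError("benefit fraction must be in [0, 1]")
    if rr_full < 1.0:
        raise ValueError("rr_full must be >= 1")
    return 1.0 + benefit_fraction * (rr_full - 1.0)


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def _require_keys(section: str, data: Mapping, allowed: Sequence[str]) -> None:
    unknown = [k for k in data if k not in allowed]
    if unknown:
        raise ValueError(f"unknown keys in {section}: {unknown}")


def _bands_from_config(name: str, raw) -> BandMap:
    bands = []
    for entry in raw:
        _require_keys(name, entry, ("upper", "cost"))
        bands.append((entry["upper"], float(entry["cost"])))
    return tuple(bands)


def _bands_to_config(bands: BandMap):
    return [{"upper": u, "cost": c} for u, c in bands]


def _params_from_dict(cfg: Mapping) -> ParameterSet:
    _require_keys("config", cfg, ("clinical", "utility", "cost", "economics",
                                  "tools", "psa"))
    clin = cfg.get("clinical", {})
    _require_keys("clinical", clin, ("transfer", "effects", "survival_model"))
    transfer = TransferProbs(**clin.get("transfer", {}))
    effects = EffectParams(**clin.get("effects", {}))
    surv_cfg = clin.get("survival_model", {})
    _require_keys("clinical.survival_model", surv_cfg, ("form", "coefficients"))
    survival = SurvivalModelSpec(
        form=surv_cfg.get("form", "logit_linear"),
        coefficients=dict(surv_cfg.get("coefficients", {})))

    utility = UtilityParams(**cfg.get("utility", {}))

    cost_cfg = dict(cfg.get("cost", {}))
    for key in ("blunt_treatment_bands", "penetrating_treatment_bands"):
        if key in cost_cfg:
            cost_cfg[key] = _bands_from_config(f"cost.{key}", cost_cfg[key])
    costs = CostParams(**cost_cfg)

    econ_cfg = dict(cfg.get("economics", {}))
    if "maicers" in econ_cfg:
        econ_cfg["maicers"] = tuple(float(m) for m in econ_cfg["maicers"])
    econ = EconSettings(**econ_cfg)

    tools = tuple(TriageTool(**t) for t in cfg.get("tools", []))
    psa = PsaSettings(**cfg.get("psa", {}))
    return ParameterSet(transfer=transfer, effects=effects, utility=utility,
                        costs=costs, econ=econ, survival=survival,
                        tools=tools, psa=psa)


def _params_to_dict(ps: ParameterSet) -> dict:
    return {
        "clinical": {
            "transfer": dataclasses.asdict(ps.transfer),
            "effects": dataclasses.asdict(ps.effects),
            "survival_model": {"form": ps.survival.form,
                               "coefficients": dict(ps.survival.coefficients)},
        },
        "utility": dataclasses.asdict(ps.utility),
        "cost": {
            **{k: v for k, v in dataclasses.asdict(ps.costs).items()
               if not k.endswith("bands")},
            "blunt_treatment_bands": _bands_to_config(ps.costs.blunt_treatment_bands),
            "penetrating_treatment_bands":
                _bands_to_config(ps.costs.penetrating_treatment_bands),
        },
        "economics": {"discount_rate": ps.econ.discount_rate,
                      "maicers": list(ps.econ.maicers),
                      "horizon_age_cap": ps.econ.horizon_age_cap},
        "tools": [dataclasses.asdict(t) for t in ps.tools],
        "psa": dataclasses.asdict(ps.psa),
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    merged = dict(base)
    for key, value in override.items():
        if (key in merged and isinstance(merged[key], dict)
                and isinstance(value, Mapping)):
            merged[key] = _deep_merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def load_parameters(source=None) -> ParameterSet:
    """Load and validate a parameter set.

    ``source`` may be None (packaged defaults), a path to a YAML file, a YAML
    string, or an already-parsed mapping. Partial configurations are merged
    over the packaged defaults (lists, e.g. tools or cost bands, replace
    wholesale). Unknown keys are rejected and all invariants (probability
    bounds, band-map coverage, positivity) enforced.
    """
    default_cfg = yaml.safe_load(resources.files("triagesim.data")
                                 .joinpath("default_params.yaml").read_text())
    if source is None:
        cfg = default_cfg
    elif isinstance(source, Mapping):
        cfg = _deep_merge(default_cfg, source)
    else:
        path = Path(source)
        if path.exists():
            cfg = _deep_merge(default_cfg, yaml.safe_load(path.read_text()))
        elif isinstance(source, str) and "\n" in source:
            cfg = _deep_merge(default_cfg, yaml.safe_load(io.StringIO(source)))
        else:
            raise FileNotFoundError(f"parameter file not found: {source}")
    if not isinstance(cfg, Mapping):
        raise ValueError("parameter config must be a mapping")
    return _params_from_dict(cfg)


def default_parameters() -> ParameterSet:
    """The packaged default parameter set (all point estimates)."""
    return load_parameters(None)


def save_parameters(ps: ParameterSet, path) -> None:
    """Write a parameter set as YAML; round-trips losslessly via load_parameters."""
    Path(path).write_text(yaml.safe_dump(_params_to_dict(ps), sort_keys=False))


# ---------------------------------------------------------------------------
# PSA machinery
# ---------------------------------------------------------------------------

def psa_distributions(ps: ParameterSet) -> dict[str, DistributionSpec]:
    """Moment-matched PSA distribution for every uncertain parameter.

    Keys are dotted paths into the parameter set. The general-population
    utility-regression coefficients, the assumption RR of 1 for ISS < 16,
    and economic settings are fixed by design.
    """
    f = ps.psa.default_se_frac
    d: dict[str, DistributionSpec] = {}
    for name in ("tp", "fn", "tn", "fp"):
        m = getattr(ps.transfer, name)
        d[f"transfer.{name}"] = DistributionSpec.for_probability(m, se=f * m)
    e = ps.effects
    d["effects.rr_death30_local_iss16"] = DistributionSpec.for_ratio(
        e.rr_death30_local_iss16, f * e.rr_death30_local_iss16)
    d["effects.rr_1yr_local_iss16"] = DistributionSpec.for_ratio(
        e.rr_1yr_local_iss16, f * e.rr_1yr_local_iss16)
    d["effects.hr_longterm_issLT16"] = DistributionSpec.for_ratio(
        e.hr_longterm_issLT16, f * e.hr_longterm_issLT16)
    d["effects.hr_longterm_iss16"] = DistributionSpec.for_ratio(
        e.hr_longterm_iss16, f * e.hr_longterm_iss16)
    d["effects.p_death_30d_1yr_iss16"] = DistributionSpec.for_probability(
        e.p_death_30d_1yr_iss16, se=f * e.p_death_30d_1yr_iss16)
    d["effects.p_death_30d_1yr_issLT16"] = DistributionSpec.for_probability(
        e.p_death_30d_1yr_issLT16, se=f * e.p_death_30d_1yr_issLT16)
    d["utility.u_iss9plus"] = DistributionSpec.for_probability(
        ps.utility.u_iss9plus, se=f * ps.utility.u_iss9plus)
    c = ps.costs
    for name in ("transfer_cost", "mtc_admit_iss16", "mtc_admit_iss9to15",
                 "post_discharge_6mo"):
        m = getattr(c, name)
        d[f"costs.{name}"] = DistributionSpec.for_cost(m, f * m)
    d["costs.longterm_mult_iss16"] = DistributionSpec.for_ratio(
        c.longterm_mult_iss16, f * c.longterm_mult_iss16)
    d["costs.longterm_mult_issLT16"] = DistributionSpec.for_ratio(
        c.longterm_mult_issLT16, f * c.longterm_mult_issLT16)
    for kind, bands in (("blunt", c.blunt_treatment_bands),
                        ("penetrating", c.penetrating_treatment_bands)):
        for i, (_, cost) in enumerate(bands):
            d[f"costs.{kind}_band{i}"] = DistributionSpec.for_cost(cost, f * cost)
    # default_se_frac = 0 disables the whole PSA (every spec degenerates to
    # its point estimate), including the tool accuracy draws
    for i, tool in enumerate(ps.tools):
        d[f"tools.{i}.sensitivity"] = DistributionSpec.for_probability(
            tool.sensitivity, ess=ps.psa.tool_ess_positive if f > 0 else None,
            se=0.0 if f == 0 else None)
        d[f"tools.{i}.specificity"] = DistributionSpec.for_probability(
            tool.specificity, ess=ps.psa.tool_ess_negative if f > 0 else None,
            se=0.0 if f == 0 else None)
    return d


_MAX_RESAMPLE = 100


def _draw_valid(spec: DistributionSpec, rng: np.random.Generator,
                valid) -> float:
    value = spec.draw(rng)
    for _ in range(_MAX_RESAMPLE):
        if valid(value):
            return value
        warnings.warn("invalid PSA draw resampled", RuntimeWarning)
        value = spec.draw(rng)
    raise RuntimeError("could not draw a valid parameter value")


def draw_parameters(ps: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA realisation of the parameter set.

    Every uncertain parameter is sampled from :func:`psa_distributions`; the
    ISS 9-15 scenario RRs are re-derived from the drawn full RRs with the
    stored benefit fraction so scenario PSA runs propagate RR uncertainty.
    """
    d = psa_distributions(ps)
    in01 = lambda v: 0.0 <= v <= 1.0
    pos = lambda v: v >= 0.0

    def dv(key, valid):
        return _draw_valid(d[key], rng, valid)

    transfer = TransferProbs(**{k: dv(f"transfer.{k}", in01)
                                for k in ("tp", "fn", "tn", "fp")})
    rr30 = dv("effects.rr_death30_local_iss16", pos)
    rr1yr = dv("effects.rr_1yr_local_iss16", pos)
    frac = ps.effects.benefit_fraction_9to15
    effects = replace(
        ps.effects,
        rr_death30_local_iss16=rr30,
        rr_1yr_local_iss16=rr1yr,
        hr_longterm_issLT16=dv("effects.hr_longterm_issLT16", pos),
        hr_longterm_iss16=dv("effects.hr_longterm_iss16", pos),
        p_death_30d_1yr_iss16=dv("effects.p_death_30d_1yr_iss16", in01),
        p_death_30d_1yr_issLT16=dv("effects.p_death_30d_1yr_issLT16", in01),
        rr_death30_local_iss9to15=interpolated_rr(max(rr30, 1.0), frac),
        rr_1yr_local_iss9to15=interpolated_rr(max(rr1yr, 1.0), frac),
    )
    utility = replace(ps.utility, u_iss9plus=dv("utility.u_iss9plus", in01))

    def draw_bands(kind, bands):
        return tuple((upper, dv(f"costs.{kind}_band{i}", pos))
                     for i, (upper, _) in enumerate(bands))

    costs = replace(
        ps.costs,
        transfer_cost=dv("costs.transfer_cost", pos),
        mtc_admit_iss16=dv("costs.mtc_admit_iss16", pos),
        mtc_admit_iss9to15=dv("costs.mtc_admit_iss9to15", pos),
        post_discharge_6mo=dv("costs.post_discharge_6mo", pos),
        longterm_mult_iss16=dv("costs.longterm_mult_iss16", pos),
        longterm_mult_issLT16=dv("costs.longterm_mult_issLT16", pos),
        blunt_treatment_bands=draw_bands("blunt", ps.costs.blunt_treatment_bands),
        penetrating_treatment_bands=draw_bands(
            "penetrating", ps.costs.penetrating_treatment_bands),
    )
    tools = tuple(
        replace(t,
                sensitivity=dv(f"tools.{i}.sensitivity", in01),
                specificity=dv(f"tools.{i}.specificity", in01))
        for i, t in enumerate(ps.tools))
    return replace(ps, transfer=transfer, effects=effects, utility=utility,
                   costs=costs, tools=tools)
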