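"""Incremental cost-effectiveness analysis and scenario machinery.

Strategies are ordered by effectiveness (QALYs); strictly dominated
strategies (another strategy is at least as effective and no more costly,
strictly better on one axis) and extendedly dominated strategies (a blend of
two others would deliver the same QALYs more cheaply — the strategy lies
above the lower convex hull in cost-QALY space) are removed, and ICERs are
computed between consecutive remaining strategies. The cost-effective
strategy at a willingness-to-pay threshold (MAICER) is the most effective
frontier member whose ICER does not exceed the threshold — equivalently the
net-monetary-benefit maximiser.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import StrategyOutcome
from .parameters import ParameterSet, interpolated_rr

__all__ = ["FrontierEntry", "Frontier", "incremental_analysis",
           "cost_effective_at", "scenario_iss9to15_benefit",
           "tariff_threshold_grid"]

COMPARATOR = "comparator"
ON_FRONTIER = "on-frontier"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly dominated"


@dataclass(frozen=True)
class FrontierEntry:
    label: str
    qalys: float
    costs: float
    status: str
    icer: float | None = None  # vs the previous frontier member


@dataclass(frozen=True)
class Frontier:
    """All strategies, ordered by QALYs ascending, with dominance status."""

    entries: tuple[FrontierEntry, ...]

    @property
    def frontier(self) -> tuple[FrontierEntry, ...]:
        return tuple(e for e in self.entries
                     if e.status in (COMPARATOR, ON_FRONTIER))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"strategy": e.label, "qalys": e.qalys,
                              "costs": e.costs, "status": e.status,
                              "icer": e.icer} for e in self.entries])


def _as_points(outcomes) -> list[tuple[str, float, float]]:
    points = []
    for o in outcomes:
        if isinstance(o, StrategyOutcome):
            points.append((o.label, float(o.mean_qalys), float(o.mean_costs)))
        else:
            label, q, c = o
            points.append((str(label), float(q), float(c)))
    if not points:
        raise ValueError("no strategies given")
    for label, q, c in points:
        if not (np.isfinite(q) and np.isfinite(c)):
            raise ValueError(f"non-finite QALYs/costs for {label}")
    return points


def incremental_analysis(outcomes) -> Frontier:
    """Full incremental analysis over a set of strategies.

    ``outcomes`` is a sequence of :class:`StrategyOutcome` or
    ``(label, qalys, costs)`` tuples. Exact ties in both QALYs and costs are
    broken by input order (the first stays, later duplicates are marked
    dominated); ties in QALYs alone leave the cheaper strategy.
    """
    points = _as_points(outcomes)
    order = sorted(range(len(points)),
                   key=lambda i: (points[i][1], points[i][2], i))
    labels = [points[i][0] for i in order]
    q = np.array([points[i][1] for i in order])
    c = np.array([points[i][2] for i in order])
    n = len(order)

    status = [ON_FRONTIER] * n
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            better = q[j] >= q[i] and c[j] <= c[i]
            strict = q[j] > q[i] or c[j] < c[i]
            tie = q[j] == q[i] and c[j] == c[i] and j < i
            if better and (strict or tie):
                status[i] = DOMINATED
                break

    # extended dominance: ICERs along the remaining strategies must increase
    while True:
        idx = [i for i in range(n) if status[i] == ON_FRONTIER]
        if len(idx) < 3:
            break
        icers = [(c[b] - c[a]) / (q[b] - q[a])
                 for a, b in zip(idx, idx[1:])]
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                status[idx[k + 1]] = EXT_DOMINATED
                removed = True
                break
        if not removed:
            break

    entries = []
    prev = None
    for pos, i in enumerate(range(n)):
        if status[i] != ON_FRONTIER:
            entries.append(FrontierEntry(labels[i], q[i], c[i], status[i]))
            continue
        if prev is None:
            entries.append(FrontierEntry(labels[i], q[i], c[i], COMPARATOR))
        else:
            icer = (c[i] - c[prev]) / (q[i] - q[prev])
            entries.append(FrontierEntry(labels[i], q[i], c[i], ON_FRONTIER,
                                         icer=icer))
        prev = i
    return Frontier(tuple(entries))


def cost_effective_at(frontier: Frontier, maicer: float) -> str:
    """Label of the cost-effective strategy at the given MAICER.

    The most effective frontier strategy whose ICER is at or below the
    threshold; the comparator if none qualifies. Equals the net-monetary-
    benefit argmax over all strategies.
    """
    if maicer <= 0:
        raise ValueError("MAICER must be positive")
    chosen = None
    for e in frontier.frontier:
        if e.status == COMPARATOR:
            chosen = e
        elif e.icer is not None and e.icer <= maicer:
            chosen = e
    if chosen is None:  # single-strategy frontier with no comparator cannot occur
        raise ValueError("frontier has no comparator")
    return chosen.label


def scenario_iss9to15_benefit(params: ParameterSet, fraction: float) -> ParameterSet:
    """Parameter set granting ISS 9-15 patients a fraction of the MTC benefit.

    The 30-day and 30-day-to-1-year local-hospital relative risks for ISS
    9-15 are interpolated linearly between 1 (no benefit) and the full ISS
    >= 16 values: at 50% the 1-year RR is 1 + 0.5*(1.64 - 1) = 1.32.
    """
    effects = replace(
        params.effects,
        benefit_fraction_9to15=fraction,
        rr_death30_local_iss9to15=interpolated_rr(
            params.effects.rr_death30_local_iss16, fraction),
        rr_1yr_local_iss9to15=interpolated_rr(
            params.effects.rr_1yr_local_iss16, fraction),
    )
    return replace(params, effects=effects)


def tariff_threshold_grid(outcomes: list[StrategyOutcome], params: ParameterSet,
                          iss16_tariffs, iss9to15_tariffs,
                          maicers=None) -> pd.DataFrame:
    """Cost-effective tool under alternative MTC admission tariffs.

    Tariffs enter the cost ledger additively (once per patient ever treated
    at an MTC, by ISS band) and do not affect survival, so simulated
    outcomes are re-costed exactly:
    ``cost' = cost + f16*(t16 - base16) + f9*(t9 - base9)`` with ``f16``/``f9``
    the per-patient probabilities of MTC care in each band. Returns one row
    per (ISS >= 16 tariff, ISS 9-15 tariff, MAICER) with the selected tool.
    """
    maicers = list(maicers) if maicers is not None else list(params.econ.maicers)
    if any(t < 0 for t in list(iss16_tariffs) + list(iss9to15_tariffs)):
        raise ValueError("tariffs must be non-negative")
    base16 = params.costs.mtc_admit_iss16
    base9 = params.costs.mtc_admit_iss9to15
    rows = []
    for t16 in iss16_tariffs:
        for t9 in iss9to15_tariffs:
            points = [(o.label, o.mean_qalys,
                       o.mean_costs
                       + o.frac_evermtc_iss16 * (t16 - base16)
                       + o.frac_evermtc_iss9to15 * (t9 - base9))
                      for o in outcomes]
            frontier = incremental_analysis(points)
            for m in maicers:
                rows.append({"iss16_tariff": t16, "iss9to15_tariff": t9,
                             "maicer": m,
                             "cost_effective_tool": cost_effective_at(frontier, m)})
    return pd.DataFrame(rows)
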