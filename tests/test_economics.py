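import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triagesim.economics import (COMPARATOR, DOMINATED, EXT_DOMINATED,
                                 ON_FRONTIER, cost_effective_at,
                                 incremental_analysis,
                                 scenario_iss9to15_benefit,
                                 tariff_threshold_grid)
from triagesim.engine import StrategyOutcome


# -- independent brute-force oracles ----------------------------------------

def brute_force_kept(points):
    """A strategy is kept iff no single strategy or two-strategy blend
    delivers at least its QALYs at no more than its cost (strictly better
    somewhere, or matching it exactly via a blend/tie)."""
    kept = []
    for i, (_, qi, ci) in enumerate(points):
        removed = False
        for j, (_, qj, cj) in enumerate(points):
            if j == i:
                continue
            if qj >= qi and cj <= ci and (qj > qi or cj < ci or j < i):
                removed = True
                break
        if not removed:
            for j, (_, qj, cj) in enumerate(points):
                for k, (_, qk, ck) in enumerate(points):
                    if i in (j, k) or not (qj < qi < qk):
                        continue
                    w = (qi - qj) / (qk - qj)
                    blend_cost = (1 - w) * cj + w * ck
                    if blend_cost <= ci:
                        removed = True
                        break
                if removed:
                    break
        if not removed:
            kept.append(i)
    return kept


def nmb_argmax(points, maicer):
    nmb = [maicer * q - c for (_, q, c) in points]
    return points[int(np.argmax(nmb))][0]


def random_points(rng, n):
    return [(f"S{i}", float(rng.uniform(10, 15)), float(rng.uniform(1e4, 5e4)))
            for i in range(n)]


class TestIncrementalAnalysis:
    def test_worked_extended_dominance_example(self):
        """C lies above the A-B segment: extendedly dominated; ICER(A->B)=100."""
        frontier = incremental_analysis([
            ("A", 10.0, 100.0), ("C", 10.5, 190.0), ("B", 11.0, 200.0)])
        status = {e.label: e.status for e in frontier.entries}
        assert status == {"A": COMPARATOR, "C": EXT_DOMINATED, "B": ON_FRONTIER}
        icers = {e.label: e.icer for e in frontier.entries if e.icer}
        assert icers["B"] == pytest.approx(100.0)

    def test_single_strategy_is_comparator(self):
        frontier = incremental_analysis([("only", 10.0, 50.0)])
        assert frontier.entries[0].status == COMPARATOR
        assert frontier.entries[0].icer is None

    def test_equal_qalys_higher_cost_dominated(self):
        frontier = incremental_analysis([("A", 10.0, 100.0), ("B", 10.0, 150.0)])
        status = {e.label: e.status for e in frontier.entries}
        assert status["B"] == DOMINATED
        assert status["A"] == COMPARATOR

    def test_exact_tie_broken_by_input_order(self):
        frontier = incremental_analysis([("first", 10.0, 100.0),
                                         ("second", 10.0, 100.0)])
        status = {e.label: e.status for e in frontier.entries}
        assert status == {"first": COMPARATOR, "second": DOMINATED}

    def test_frontier_icers_strictly_increase(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            frontier = incremental_analysis(random_points(rng, 6))
            icers = [e.icer for e in frontier.frontier if e.icer is not None]
            assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_agrees_with_brute_force_hull(self):
        rng = np.random.default_rng(29)
        for _ in range(300):
            points = random_points(rng, int(rng.integers(1, 7)))
            frontier = incremental_analysis(points)
            kept = {points[i][0] for i in brute_force_kept(points)}
            mine = {e.label for e in frontier.frontier}
            assert mine == kept

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(31)
        points = random_points(rng, 6)
        base = incremental_analysis(points).to_frame()
        for _ in range(5):
            perm = [points[i] for i in rng.permutation(6)]
            shuffled = incremental_analysis(perm).to_frame()
            merged = base.merge(shuffled, on="strategy", suffixes=("_a", "_b"))
            assert (merged["status_a"] == merged["status_b"]).all()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            incremental_analysis([("A", np.nan, 100.0)])


class TestCostEffectiveAt:
    def test_below_first_icer_chooses_comparator(self):
        frontier = incremental_analysis([("A", 10.0, 100.0), ("B", 11.0, 200.0)])
        assert cost_effective_at(frontier, 50.0) == "A"

    def test_boundary_maicer_inclusive(self):
        frontier = incremental_analysis([("A", 10.0, 100.0), ("B", 11.0, 200.0)])
        assert cost_effective_at(frontier, 100.0) == "B"

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(deadline=None, max_examples=100)
    def test_equals_nmb_argmax(self, seed):
        rng = np.random.default_rng(seed)
        points = random_points(rng, int(rng.integers(2, 7)))
        maicer = float(rng.uniform(100, 1e5))
        frontier = incremental_analysis(points)
        assert cost_effective_at(frontier, maicer) == nmb_argmax(points, maicer)

    def test_nonpositive_maicer_rejected(self):
        frontier = incremental_analysis([("A", 10.0, 100.0)])
        with pytest.raises(ValueError):
            cost_effective_at(frontier, 0.0)


class TestScenario:
    @pytest.mark.parametrize("fraction,rr30,rr1yr", [
        (0.0, 1.0, 1.0),
        (0.25, 1.0625, 1.16),
        (0.50, 1.125, 1.32),
        (0.75, 1.1875, 1.48),
        (1.0, 1.25, 1.64),
    ])
    def test_interpolated_benefit(self, params, fraction, rr30, rr1yr):
        ps = scenario_iss9to15_benefit(params, fraction)
        assert ps.effects.rr_death30_local_iss9to15 == pytest.approx(rr30)
        assert ps.effects.rr_1yr_local_iss9to15 == pytest.approx(rr1yr)
        # base-case groups untouched
        assert ps.effects.rr_death30_local_iss16 == 1.25
        assert ps.effects.rr_death30_local_issLT16 == 1.0

    def test_fraction_out_of_range(self, params):
        with pytest.raises(ValueError):
            scenario_iss9to15_benefit(params, 1.5)


def _outcome(label, qalys, costs, f16=0.05, f9=0.03):
    return StrategyOutcome(
        label=label, sensitivity=0.5, specificity=0.5,
        mtc_per_100k=0.0, mtc_iss16_per_100k=0.0, mtc_issLT16_per_100k=0.0,
        p_death_30d=0.05, p_death_30d_1yr=0.02, mean_life_years=32.0,
        mean_qalys=qalys, mean_costs=costs,
        frac_evermtc_iss16=f16, frac_evermtc_iss9to15=f9)


class TestTariffGrid:
    def test_base_tariffs_reproduce_base_answer(self, params):
        outcomes = [_outcome("A", 13.58, 33000.0), _outcome("B", 13.60, 33400.0)]
        grid = tariff_threshold_grid(outcomes, params, [2819.0], [1466.0],
                                     maicers=[20000.0, 30000.0])
        base = incremental_analysis(outcomes)
        for _, row in grid.iterrows():
            assert row["cost_effective_tool"] == cost_effective_at(
                base, row["maicer"])

    def test_zero_tariffs_remove_premium_exactly(self, params):
        outs = [_outcome("A", 13.58, 33000.0, f16=0.06, f9=0.02),
                _outcome("B", 13.60, 33100.0, f16=0.09, f9=0.01)]
        grid = tariff_threshold_grid(outs, params, [0.0], [0.0],
                                     maicers=[20000.0])
        repriced = [(o.label, o.mean_qalys,
                     o.mean_costs - o.frac_evermtc_iss16 * 2819.0
                     - o.frac_evermtc_iss9to15 * 1466.0) for o in outs]
        manual = cost_effective_at(incremental_analysis(repriced), 20000.0)
        assert grid["cost_effective_tool"].iloc[0] == manual
        assert grid.shape[0] == 1

    def test_cheaper_mtc_care_never_lowers_chosen_sensitivity(self, params):
        """Economic monotonicity: as MTC tariffs fall, the selected tool's
        sensitivity cannot fall (MTC care becomes relatively better value)."""
        # synthetic tools: QALYs and MTC exposure rise with sensitivity
        outcomes = []
        for i, s in enumerate(np.linspace(0.3, 0.99, 6)):
            outcomes.append(_outcome(
                f"sens{s:.2f}", 13.5 + 0.02 * s, 33000 + 3000 * s,
                f16=0.05 + 0.04 * s, f9=0.02 + 0.3 * s * 0.1))
        sens_of = {o.label: float(o.label[4:]) for o in outcomes}
        for m in (20000.0, 30000.0):
            prev = None
            for t16 in (2819.0, 2114.25, 1409.5, 704.75, 0.0):
                grid = tariff_threshold_grid(outcomes, params, [t16], [1466.0],
                                             maicers=[m])
                chosen = sens_of[grid["cost_effective_tool"].iloc[0]]
                if prev is not None:
                    assert chosen >= prev - 1e-12
                prev = chosen

    def test_negative_tariff_rejected(self, params):
        with pytest.raises(ValueError):
            tariff_threshold_grid([_outcome("A", 13.5, 3e4)], params,
                                  [-1.0], [0.0])
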