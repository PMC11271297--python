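"""ICERs, frontier analysis, NMB, currency conversion, threshold search."""

import numpy as np
import pytest

from her2cua import (
    NOT_ACHIEVABLE,
    CostComponent,
    Perspective,
    icer,
    incremental_analysis,
    nmb,
    threshold_reduction,
    to_usd,
)
from her2cua.economics import DominatedError, UndefinedICERError
from her2cua.engine import EconResult


def _result(sid, cost, qaly, ly=None, perspective=Perspective.PUBLIC):
    ly = qaly / 0.8 if ly is None else ly
    return EconResult(
        strategy_id=sid,
        perspective=perspective,
        ly_discounted=ly,
        qaly_discounted=qaly,
        cost_discounted=cost,
        ly_undiscounted=ly,
        qaly_undiscounted=qaly,
        cost_undiscounted=cost,
        per_cycle_cost_stream=np.zeros(1),
    )


class TestIcer:
    def test_published_rounded_totals(self):
        """Arithmetic on the printed rounded totals for S2 vs the comparator
        reproduces the printed ICER to rounding error."""
        per_qaly, per_ly = icer(
            _result("S2", 4_885_031.0, 9.13, ly=11.03),
            _result("S1", 2_882_178.0, 7.27, ly=8.87),
        )
        assert per_qaly == pytest.approx(1_076_802.7, abs=1.0)
        assert per_qaly == pytest.approx(1_074_254.0, rel=0.005)
        assert per_ly == pytest.approx(2_002_853.0 / 2.16, rel=1e-6)

    def test_zero_qaly_difference(self):
        with pytest.raises(UndefinedICERError):
            icer(_result("A", 10.0, 1.0), _result("B", 20.0, 1.0))

    def test_dominance_is_not_an_icer(self):
        with pytest.raises(DominatedError):
            icer(_result("A", 10.0, 2.0), _result("B", 20.0, 1.0))

    def test_perspective_mismatch(self):
        with pytest.raises(ValueError):
            icer(
                _result("A", 10.0, 2.0),
                _result("B", 5.0, 1.0, perspective=Perspective.SOCIETAL),
            )


class TestNmb:
    def test_comparator_value(self):
        assert nmb(_result("S1", 2_882_178.0, 7.27), 758_680.0) == pytest.approx(
            2_633_425.6
        )

    def test_zero_wtp_is_negative_cost(self):
        assert nmb(_result("A", 123.0, 4.0), 0.0) == -123.0

    def test_degenerate_zero(self):
        assert nmb(_result("A", 0.0, 0.0), 758_680.0) == 0.0

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            nmb(_result("A", 1.0, 1.0), -1.0)


class TestToUsd:
    def test_unit_rate(self):
        assert to_usd(194.78) == pytest.approx(1.0)

    def test_comparator_lifetime_cost(self):
        # the printed USD figure for the comparator's lifetime cost
        assert to_usd(2_882_178.0) == pytest.approx(14_797.0, abs=0.5)

    def test_zero(self):
        assert to_usd(0.0) == 0.0


class TestIncrementalAnalysis:
    def test_base_case_cost_ordering(self, public_results, societal_results):
        for results in (public_results, societal_results):
            table = incremental_analysis(results)
            assert list(table.strategy_id) == ["S1", "S3", "S5", "S2", "S4"]
            assert table.total_cost.is_monotonic_increasing

    def test_sequential_icers_match_pairwise_differences(self, societal_results):
        table = incremental_analysis(societal_results, wtp=758_680.0)
        s2 = table[table.strategy_id == "S2"].iloc[0]
        expected = (
            societal_results["S2"].cost_discounted
            - societal_results["S5"].cost_discounted
        ) / (
            societal_results["S2"].qaly_discounted
            - societal_results["S5"].qaly_discounted
        )
        assert s2.sequential_icer == pytest.approx(expected, rel=1e-12)

    def test_extended_dominance_flagged_but_tabulated(self, societal_results):
        """S5 costs more per QALY than the next strategy up the frontier, so
        it is extendedly dominated yet keeps its row and sequential ICER."""
        table = incremental_analysis(societal_results)
        s5 = table[table.strategy_id == "S5"].iloc[0]
        assert s5.dominance == "extendedly_dominated"
        assert np.isfinite(s5.sequential_icer)

    def test_frontier_icers_nondecreasing(self, societal_results):
        table = incremental_analysis(societal_results)
        frontier = table[table.dominance == "none"]
        icers = frontier.sequential_icer.dropna().to_numpy()
        assert np.all(np.diff(icers) >= 0.0)

    def test_strict_dominance_constructed(self):
        table = incremental_analysis(
            [_result("A", 100.0, 1.0), _result("B", 200.0, 0.5)], comparator="A"
        )
        row_b = table[table.strategy_id == "B"].iloc[0]
        assert row_b.dominance == "dominated"

    def test_nmb_agrees_with_icer_decision(self, societal_results):
        """At any threshold the top-NMB strategy is weakly preferred under
        the pairwise ICER rule for every rival."""
        for wtp in (0.0, 500_000.0, 758_680.0, 2_000_000.0, 5_000_000.0):
            table = incremental_analysis(societal_results, wtp=wtp)
            best = table.loc[table.nmb.idxmax()]
            for _, row in table.iterrows():
                if row.strategy_id == best.strategy_id:
                    continue
                d_cost = best.total_cost - row.total_cost
                d_qaly = best.total_qaly - row.total_qaly
                assert d_cost <= wtp * d_qaly + 1e-6

    def test_missing_comparator_rejected(self, societal_results):
        with pytest.raises(ValueError):
            incremental_analysis(societal_results, comparator="S9")


class TestThresholdReduction:
    def test_already_cost_effective_needs_no_reduction(self, base_params):
        assert (
            threshold_reduction(base_params, "S3", "S1", Perspective.SOCIETAL) == 0.0
        )

    def test_neoadjuvant_only_not_achievable_for_dual_adjuvant(self, base_params):
        result = threshold_reduction(base_params, "S4", "S1", Perspective.SOCIETAL)
        assert result is NOT_ACHIEVABLE

    def test_joint_reduction_rescues_dual_adjuvant(self, base_params):
        """Scaling the adjuvant-phase excess as well makes a full-range
        search succeed where the neoadjuvant-only one cannot."""
        result = threshold_reduction(
            base_params,
            "S4",
            "S1",
            Perspective.SOCIETAL,
            components=(CostComponent.NEOADJUVANT, CostComponent.ADJUVANT_EF_YEAR1),
            step=0.25,
        )
        assert result is not NOT_ACHIEVABLE

    def test_monotone_in_wtp(self, base_params):
        low = threshold_reduction(
            base_params, "S2", "S1", Perspective.SOCIETAL, wtp=700_000.0, step=0.25
        )
        high = threshold_reduction(
            base_params, "S2", "S1", Perspective.SOCIETAL, wtp=1_500_000.0, step=0.25
        )
        assert high <= low

    def test_bisect_consistent_with_grid(self, base_params):
        grid = threshold_reduction(base_params, "S2", "S1", Perspective.SOCIETAL)
        cont = threshold_reduction(
            base_params, "S2", "S1", Perspective.SOCIETAL, method="bisect"
        )
        assert cont <= grid + 1e-9
        assert grid - cont < 0.05 + 1e-9

    def test_self_comparison_rejected(self, base_params):
        with pytest.raises(ValueError):
            threshold_reduction(base_params, "S2", "S2", Perspective.SOCIETAL)

    def test_step_must_divide_one(self, base_params):
        with pytest.raises(ValueError):
            threshold_reduction(
                base_params, "S2", "S1", Perspective.SOCIETAL, step=0.3
            )
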