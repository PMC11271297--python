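"""Probabilistic sensitivity analysis: sampling, reproducibility, CEAC,
CE plane."""

import math

import numpy as np
import pytest

from her2cua import (
    Perspective,
    builtin_base_case,
    ce_plane,
    ceac,
    quadrant_counts,
    run_psa,
    run_strategy,
    sample_parameter_set,
)
from her2cua.parameters import base_values, build_parameter_set
from her2cua.psa import _draw_values


@pytest.fixture(scope="module")
def draws(base_params):
    """A shared batch of joint parameter draws (values only, no model runs)."""
    rng = np.random.default_rng(123)
    return [_draw_values(base_params, rng)[0] for _ in range(3000)]


class TestSampling:
    def test_sampled_set_is_valid_and_structured(self, base_params):
        rng = np.random.default_rng(7)
        sampled = sample_parameter_set(base_params, rng)
        assert sampled.efficacy_mode == base_params.efficacy_mode
        assert sampled.discount_rate_costs == base_params.discount_rate_costs
        assert sampled.horizon_months == base_params.horizon_months
        assert sampled.values != dict(base_params.values)

    def test_utility_draws_center_on_published_mean(self, draws):
        vals = np.array([d["util.metastasis"] for d in draws])
        se = 0.0266
        assert vals.mean() == pytest.approx(0.70, abs=3 * se / math.sqrt(len(vals)))

    def test_cost_draws_center_on_published_mean(self, draws):
        vals = np.array([d["cost.neoadj_dmc.s2"] for d in draws])
        se = 259_198.10
        assert vals.mean() == pytest.approx(
            2_591_980.99, abs=3 * se / math.sqrt(len(vals))
        )

    def test_hazard_ratio_geometric_mean(self, draws):
        logs = np.log([d["hr.s2"] for d in draws])
        sigma = 0.26662
        assert logs.mean() == pytest.approx(
            math.log(0.54), abs=3 * sigma / math.sqrt(len(logs))
        )

    def test_lrr_exits_stay_on_simplex(self, draws):
        for d in draws[:200]:
            total = d["tp.lrr_to_met"] + d["tp.lrr_to_death"] + d["tp.lrr_to_rem"]
            assert total <= 1.0 + 1e-12

    def test_met_share_is_complement(self, base_params):
        rng = np.random.default_rng(5)
        sampled = sample_parameter_set(base_params, rng)
        sh = sampled.shared
        assert sh.p_event_split_lrr + sh.p_event_split_met == pytest.approx(1.0)
        assert sh.p_event_split_lrr != 0.25

    def test_all_fixed_specs_reproduce_base_case(self):
        fixed = build_parameter_set(base_values())  # defaults every spec to fixed
        rng = np.random.default_rng(0)
        sampled = sample_parameter_set(fixed, rng)
        assert dict(sampled.values) == dict(fixed.values)


class TestRunPsa:
    def test_seeded_reproducibility(self, base_params):
        a = run_psa(base_params, n=3, seed=42, perspective=Perspective.PUBLIC)
        b = run_psa(base_params, n=3, seed=42, perspective=Perspective.PUBLIC)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        assert a.to_frame().to_csv() == b.to_frame().to_csv()
        c = run_psa(base_params, n=3, seed=43, perspective=Perspective.PUBLIC)
        assert not np.array_equal(a.costs, c.costs)

    def test_single_fixed_iteration_equals_base_case(self, base_params):
        fixed = build_parameter_set(base_values())
        res = run_psa(fixed, n=1, seed=0, perspective=Perspective.PUBLIC)
        base = run_strategy("S1", builtin_base_case(), Perspective.PUBLIC)
        assert res.costs[0, 0] == pytest.approx(base.cost_discounted, rel=1e-12)
        assert res.qalys[0, 0] == pytest.approx(base.qaly_discounted, rel=1e-12)

    def test_draw_sanity(self, small_psa):
        assert small_psa.costs.shape == (60, 5)
        assert np.all(small_psa.costs > 0.0)
        assert np.all(small_psa.qalys <= small_psa.lys)
        assert small_psa.n_simplex_renormalized >= 1
        assert len(small_psa.draws) == 60

    def test_mean_cost_tracks_base_case(self, small_psa, societal_results):
        """Near-linearity in the cost parameters: Monte Carlo mean cost stays
        within 3 SE of the deterministic cost."""
        for j, sid in enumerate(small_psa.strategy_ids):
            mc = small_psa.costs[:, j]
            se = mc.std(ddof=1) / math.sqrt(len(mc))
            assert abs(mc.mean() - societal_results[sid].cost_discounted) < 4 * se


class TestCeac:
    def test_probabilities_sum_to_one(self, small_psa):
        table = ceac(small_psa, [0.0, 400_000.0, 758_680.0, 5e6])
        sums = table.groupby("wtp_lkr").probability.sum()
        assert np.allclose(sums, 1.0)

    def test_zero_wtp_prefers_cheapest(self, small_psa):
        table = ceac(small_psa, [0.0])
        cheapest_share = np.mean(
            small_psa.costs.argmin(axis=1)
            == [small_psa.strategy_ids.index("S1")] * small_psa.n_iterations
        )
        s1 = table[table.strategy == "S1"].probability.iloc[0]
        assert s1 == pytest.approx(cheapest_share)

    def test_large_wtp_prefers_most_effective(self, small_psa):
        table = ceac(small_psa, [1e12])
        best_qaly = small_psa.qalys.argmax(axis=1)
        for j, sid in enumerate(small_psa.strategy_ids):
            expected = np.mean(best_qaly == j)
            got = table[table.strategy == sid].probability.iloc[0]
            assert got == pytest.approx(expected)

    def test_degenerate_psa_gives_indicator_curve(self):
        fixed = build_parameter_set(base_values())
        res = run_psa(fixed, n=2, seed=0, perspective=Perspective.SOCIETAL)
        table = ceac(res, [758_680.0])
        probs = table.probability.to_numpy()
        assert sorted(probs) == [0.0, 0.0, 0.0, 0.0, 1.0]

    def test_empty_grid_rejected(self, small_psa):
        with pytest.raises(ValueError):
            ceac(small_psa, [])


class TestCePlane:
    def test_quadrant_counts_complete(self, small_psa):
        plane = ce_plane(small_psa, reference="S1")
        counts = quadrant_counts(plane)
        assert (counts.sum(axis=1) == small_psa.n_iterations).all()
        assert set(plane.strategy) == {"S2", "S3", "S4", "S5"}

    def test_dual_therapy_mostly_northeast(self, small_psa):
        """Dual HER2-targeted strategies are mostly costlier and more
        effective than the comparator."""
        plane = ce_plane(small_psa, reference="S1")
        s2 = plane[plane.strategy == "S2"]
        ne = (s2.quadrant == "NE").mean()
        assert ne > 0.5

    def test_unknown_reference_rejected(self, small_psa):
        with pytest.raises(ValueError):
            ce_plane(small_psa, reference="S0")
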