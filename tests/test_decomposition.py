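import numpy as np
import pytest

from dndea import (
    division_efficiency,
    division_period_efficiency,
    efficiency_report,
    generate_planted_frontier,
    generate_small_instance,
    period_efficiency,
    restricted_score,
    solve_all,
    solve_dmu,
    validate_dataset,
)

from conftest import long_panel, single_division_rows


class TestDegenerateIdentities:
    def test_single_division_single_period_scores_all_coincide(self, toy_b):
        spec, data = toy_b
        sol = solve_dmu(spec, data, "B")
        assert period_efficiency(sol, "t1") == pytest.approx(0.8, abs=1e-9)
        assert division_efficiency(sol, "d") == pytest.approx(0.8, abs=1e-9)
        assert division_period_efficiency(sol, "d", "t1") == pytest.approx(0.8, abs=1e-9)
        assert sol.theta == pytest.approx(0.8, abs=1e-9)

    def test_single_division_period_score_equals_division_period_score(self):
        # K = 1, T = 2: per-period score must equal the (k=1, t) cell score
        spec, data, _ = generate_small_instance(5)
        assert data.n_periods == 2 and len(spec.divisions) == 1
        for dmu in data.dmu_ids:
            sol = solve_dmu(spec, data, dmu)
            for t in data.periods:
                assert period_efficiency(sol, t) == pytest.approx(
                    division_period_efficiency(sol, "d", t), abs=1e-12
                )

    def test_all_efficient_solution_scores_one_everywhere(self, toy_a):
        spec, data = toy_a
        sol = solve_dmu(spec, data, "A")
        assert period_efficiency(sol, "t1") == pytest.approx(1.0, abs=1e-9)
        assert division_period_efficiency(sol, "d", "t1") == pytest.approx(1.0, abs=1e-9)

    def test_two_period_single_dmu_is_efficient_in_both_periods(self, minimal_spec):
        rows = single_division_rows(
            {"A": {("x", "input"): [2.0, 3.0], ("y", "good_output"): [1.0, 2.0]}},
            periods=("t1", "t2"),
        )
        data = validate_dataset(minimal_spec, long_panel(rows))
        sol = solve_dmu(minimal_spec, data, "A")
        for t in ("t1", "t2"):
            assert period_efficiency(sol, t) == pytest.approx(1.0, abs=1e-9)


class TestMediantIdentity:
    @pytest.mark.parametrize("seed", range(1, 13))
    def test_overall_is_weighted_mediant_and_bracketed_by_period_scores(self, seed):
        spec, data, dmu = generate_small_instance(seed)
        sol = solve_dmu(spec, data, dmu)
        wt = sol.period_weights
        wk = sol.division_weights
        num_t = {t: sum(wk[k] * sol.num_parts[(k, t)] for k in wk) for t in wt}
        den_t = {t: sum(wk[k] * sol.den_parts[(k, t)] for k in wk) for t in wt}
        mediant = sum(wt[t] * num_t[t] for t in wt) / sum(wt[t] * den_t[t] for t in wt)
        assert sol.theta == pytest.approx(mediant, abs=1e-7)
        period_scores = [period_efficiency(sol, t) for t in wt]
        assert min(period_scores) - 1e-7 <= sol.theta <= max(period_scores) + 1e-7

    def test_division_scores_bracket_overall_on_two_stage_panel(self):
        from dndea import generate_two_stage_panel

        panel = generate_two_stage_panel(n_dmu=8, n_periods=2, seed=11)
        for sol in solve_all(panel.spec, panel.data):
            div_scores = [division_efficiency(sol, k) for k in sol.divisions]
            assert min(div_scores) - 1e-7 <= sol.theta <= max(div_scores) + 1e-7


class TestReportAssembly:
    def test_report_shapes_and_score_ranges(self):
        panel = generate_planted_frontier(6, 2, n_efficient=2, seed=3)
        sols = solve_all(panel.spec, panel.data)
        report = efficiency_report(sols)
        assert report.overall.shape == (6,)
        assert report.period.shape == (6, 2)
        assert report.division.shape == (6, 1)
        assert report.division_period.shape == (6, 2)
        for frame in (report.period, report.division, report.division_period):
            assert ((frame.to_numpy() > 0) & (frame.to_numpy() <= 1 + 1e-9)).all()

    def test_unknown_labels_raise_lookup_errors(self, toy_a):
        spec, data = toy_a
        sol = solve_dmu(spec, data, "A")
        with pytest.raises(KeyError):
            period_efficiency(sol, "t9")
        with pytest.raises(KeyError):
            division_efficiency(sol, "ghost")
        with pytest.raises(KeyError):
            division_period_efficiency(sol, "d", "t9")


class TestReoptimizedScores:
    def test_reoptimized_scores_lower_or_equal_to_slack_based_scores(self):
        # re-optimizing a component's own ratio can only find a (weakly)
        # smaller minimum than evaluating it at the overall-optimal slacks
        spec, data, dmu = generate_small_instance(9)
        sol = solve_dmu(spec, data, dmu)
        for t in data.periods:
            reopt = restricted_score(spec, data, dmu, periods=[t])
            assert reopt <= period_efficiency(sol, t) + 1e-7
        reopt_overall = restricted_score(spec, data, dmu)
        assert reopt_overall == pytest.approx(sol.theta, abs=1e-7)
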