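import numpy as np
import pytest
from scipy.optimize import linprog

from dndea import (
    DivisionVariables,
    ModelSpec,
    WeightScheme,
    assemble_program,
    generate_small_instance,
    linearize,
    solve_all,
    solve_dmu,
    validate_dataset,
    validate_spec,
    verify_solution,
)
from dndea.bruteforce import grid_overall_efficiency
from dndea.engine import FAMILY_GOOD, FAMILY_INPUT

from conftest import long_panel, single_division_rows


def _lp_optimum(spec, data, dmu):
    lp = linearize(assemble_program(spec, data, dmu))
    res = linprog(lp.c, A_eq=lp.a_eq, b_eq=lp.b_eq, bounds=lp.bounds, method="highs")
    assert res.status == 0
    return res.fun


class TestToyInstances:
    def test_dominated_unit_with_excess_input_scores_half(self, toy_a):
        spec, data = toy_a
        sol = solve_dmu(spec, data, "B")
        assert sol.theta == pytest.approx(0.5, abs=1e-6)
        assert sol.slack(FAMILY_INPUT, "d", "t1", "x") == pytest.approx(1.0, abs=1e-6)
        assert sol.lam[("d", "t1")][0] == pytest.approx(1.0, abs=1e-6)  # benchmark is A

    def test_dominated_unit_with_excess_bad_output_scores_four_fifths(self, toy_b):
        spec, data = toy_b
        # numerator 1, denominator 1 + (1/2)*(1/2) at the all-A benchmark
        assert solve_dmu(spec, data, "B").theta == pytest.approx(0.8, abs=1e-6)

    def test_undominated_units_score_one_with_zero_slacks(self, toy_a, toy_b):
        for spec, data in (toy_a, toy_b):
            sol = solve_dmu(spec, data, "A")
            assert sol.theta == pytest.approx(1.0, abs=1e-6)
            assert all(s <= 1e-9 for s in sol.slacks.values())

    def test_lp_optimum_equals_fractional_optimum(self, toy_a, toy_b):
        spec_a, data_a = toy_a
        spec_b, data_b = toy_b
        assert _lp_optimum(spec_a, data_a, "B") == pytest.approx(0.5, abs=1e-9)
        assert _lp_optimum(spec_b, data_b, "B") == pytest.approx(0.8, abs=1e-9)

    def test_weight_rescaling_leaves_lp_optimum_unchanged(self, toy_b):
        spec, data = toy_b
        scaled = spec.model_copy(
            update={"weights": WeightScheme(period_weights=[10.0], division_weights=[10.0])}
        )
        assert solve_dmu(validate_spec(scaled), data, "B").theta == pytest.approx(
            0.8, abs=1e-9
        )


class TestProgramStructure:
    def test_single_dmu_program_forces_self_solution(self, minimal_spec):
        rows = single_division_rows({"A": {("x", "input"): 3.0, ("y", "good_output"): 2.0}})
        data = validate_dataset(minimal_spec, long_panel(rows))
        sol = solve_dmu(minimal_spec, data, "A")
        assert sol.theta == pytest.approx(1.0, abs=1e-9)
        assert sol.lam[("d", "t1")] == pytest.approx([1.0])
        assert verify_solution(sol, minimal_spec, data).max_residual < 1e-9

    def test_two_stage_program_has_expected_block_and_slack_counts(self):
        from dndea import build_two_stage_spec, generate_two_stage_panel

        panel = generate_two_stage_panel(n_dmu=31, n_periods=4, seed=3)
        fp = assemble_program(build_two_stage_spec(), panel.data, panel.data.dmu_ids[0])
        assert len(fp.lam_idx) == 2 * 4
        assert all(len(idx) == 31 for idx in fp.lam_idx.values())
        from collections import Counter

        families = Counter(key[0] for key in fp.slack_idx)
        assert families == {
            "input": 4 * 4, "link_in": 4 * 2, "good_output": 4 * 2,
            "bad_output": 4 * 2, "carryover": 4 * 1,
        }

    def test_unknown_dmu_raises_lookup_error(self, toy_a):
        spec, data = toy_a
        with pytest.raises(KeyError):
            assemble_program(spec, data, "ghost")

    def test_denominator_reduces_to_good_output_terms_without_bads_or_carry(
        self, toy_a
    ):
        spec, data = toy_a
        fp = assemble_program(spec, data, "B")
        den_idx = set().union(*(set(d) for d in fp.bracket_den.values()))
        assert {fp_key[0] for fp_key, i in fp.slack_idx.items() if i in den_idx} == {
            FAMILY_GOOD
        }


class TestSolveAll:
    def test_batch_scores_match_per_dmu_scores(self, toy_a):
        spec, data = toy_a
        sols = {s.dmu: s.theta for s in solve_all(spec, data)}
        assert sols == {"A": pytest.approx(1.0, abs=1e-9),
                        "B": pytest.approx(0.5, abs=1e-9)}

    def test_identical_dmus_are_all_efficient(self, minimal_spec):
        rows = single_division_rows(
            {d: {("x", "input"): 5.0, ("y", "good_output"): 3.0} for d in "ABC"}
        )
        data = validate_dataset(minimal_spec, long_panel(rows))
        for sol in solve_all(minimal_spec, data):
            assert sol.theta == pytest.approx(1.0, abs=1e-9)
            assert all(s <= 1e-9 for s in sol.slacks.values())


class TestSolutionContracts:
    @pytest.mark.parametrize("seed", range(1, 11))
    def test_bracket_identity_and_bounds_hold(self, seed):
        spec, data, dmu = generate_small_instance(seed)
        sol = solve_dmu(spec, data, dmu)
        assert 0.0 < sol.theta <= 1.0 + 1e-9
        num = sum(
            sol.period_weights[t] * sol.division_weights[k] * sol.num_parts[(k, t)]
            for (k, t) in sol.num_parts
        )
        den = sum(
            sol.period_weights[t] * sol.division_weights[k] * sol.den_parts[(k, t)]
            for (k, t) in sol.den_parts
        )
        assert sol.theta == pytest.approx(num / den, abs=1e-7)
        for kt in sol.num_parts:
            assert 0.0 < sol.num_parts[kt] <= 1.0 + 1e-9
            assert sol.den_parts[kt] >= 1.0 - 1e-9

    def test_residuals_within_tolerance_and_perturbation_flagged(self, toy_a):
        spec, data = toy_a
        sol = solve_dmu(spec, data, "B")
        assert verify_solution(sol, spec, data).passed
        sol.lam[("d", "t1")] = sol.lam[("d", "t1")] + 1e-2
        assert not verify_solution(sol, spec, data).passed


class TestInvariances:
    @pytest.mark.parametrize("seed", range(1, 9))
    def test_units_invariance_under_column_rescaling(self, seed):
        spec, data, dmu = generate_small_instance(seed)
        base = solve_dmu(spec, data, dmu).theta
        cells = spec.storage_cells()
        division, variable, _role = cells[seed % len(cells)]
        scaled = validate_dataset(spec, data.scaled(division, variable, 137.0))
        assert solve_dmu(spec, scaled, dmu).theta == pytest.approx(base, abs=1e-8)

    def test_increasing_input_of_dominated_unit_does_not_raise_score(self, toy_a):
        spec, data = toy_a
        base = solve_dmu(spec, data, "B").theta
        worse = validate_dataset(spec, data.replaced("B", "t1", "d", "x", 3.0))
        assert solve_dmu(spec, worse, "B").theta <= base + 1e-9

    def test_increasing_bad_output_of_dominated_unit_does_not_raise_score(self, toy_b):
        spec, data = toy_b
        base = solve_dmu(spec, data, "B").theta
        worse = validate_dataset(spec, data.replaced("B", "t1", "d", "b", 4.0))
        assert solve_dmu(spec, worse, "B").theta <= base + 1e-9


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(1, 26))
    def test_engine_matches_grid_enumeration_on_tiny_instances(self, seed):
        spec, data, dmu = generate_small_instance(seed)
        theta = solve_dmu(spec, data, dmu).theta
        assert theta == pytest.approx(
            grid_overall_efficiency(spec, data, dmu), abs=2e-3
        )

    def test_static_single_period_case_is_classical_vrs_sbm(self):
        # K=1, T=1, no bads/links/carry: the score must coincide with the
        # classical non-oriented VRS SBM ratio enumerated on the grid
        spec = validate_spec(
            ModelSpec(
                divisions=["d"],
                variables={"d": DivisionVariables(inputs=["x1", "x2"],
                                                  good_outputs=["y"])},
            )
        )
        rows = single_division_rows(
            {"A": {("x1", "input"): 2.0, ("x2", "input"): 6.0, ("y", "good_output"): 4.0},
             "B": {("x1", "input"): 5.0, ("x2", "input"): 3.0, ("y", "good_output"): 4.0},
             "C": {("x1", "input"): 6.0, ("x2", "input"): 7.0, ("y", "good_output"): 3.0}},
        )
        data = validate_dataset(spec, long_panel(rows))
        for dmu in "ABC":
            assert solve_dmu(spec, data, dmu).theta == pytest.approx(
                grid_overall_efficiency(spec, data, dmu), abs=2e-3
            )
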