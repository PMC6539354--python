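import numpy as np
import pytest

from dndea import (
    bad_output_factor_index,
    generate_planted_frontier,
    good_output_factor_index,
    input_factor_index,
    pivot_indices,
    solve_all,
    solve_dmu,
    tabulate_indices,
    validate_dataset,
)
from dndea.exceptions import DomainError, InconsistencyError


@pytest.mark.parametrize(
    "func, actual, slack, expected",
    [
        (input_factor_index, 10.0, 2.0, 0.8),
        (input_factor_index, 10.0, 0.0, 1.0),
        (good_output_factor_index, 8.0, 2.0, 0.8),
        (good_output_factor_index, 8.0, 0.0, 1.0),
        (bad_output_factor_index, 2.0, 1.0, 0.5),
        (bad_output_factor_index, 2.0, 0.0, 1.0),
    ],
)
def test_factor_index_formulas(func, actual, slack, expected):
    assert func(actual, slack) == pytest.approx(expected)


def test_inconsistent_slack_is_flagged_as_solver_artifact():
    with pytest.raises(InconsistencyError):
        input_factor_index(1.0, 2.0)
    with pytest.raises(InconsistencyError):
        bad_output_factor_index(1.0, 2.0)
    with pytest.raises(DomainError):
        good_output_factor_index(0.0, 1.0)


def test_toy_indices_from_optimal_slacks(toy_a, toy_b):
    spec_a, data_a = toy_a
    table = tabulate_indices(solve_all(spec_a, data_a), spec_a)
    by = table.set_index(["dmu", "variable"])["index"]
    assert by.loc[("B", "x")] == pytest.approx(0.5, abs=1e-6)  # (2-1)/2
    assert by.loc[("B", "y")] == pytest.approx(1.0, abs=1e-6)
    assert by.loc[("A", "x")] == pytest.approx(1.0, abs=1e-6)
    assert by.loc[("A", "y")] == pytest.approx(1.0, abs=1e-6)

    spec_b, data_b = toy_b
    table_b = tabulate_indices([solve_dmu(spec_b, data_b, "B")], spec_b)
    bad = table_b.set_index(["dmu", "variable"])["index"].loc[("B", "b")]
    assert bad == pytest.approx(0.5, abs=1e-6)  # (2-1)/2 at the all-A benchmark


def test_efficient_dmus_have_all_indices_one():
    panel = generate_planted_frontier(8, 2, n_efficient=3, seed=5)
    sols = solve_all(panel.spec, panel.data)
    table = tabulate_indices(sols, panel.spec)
    eff = table[table["dmu"].isin(panel.planted_efficient_ids)]
    assert np.allclose(eff["index"], 1.0, atol=1e-6)
    # and a unit with division-period score 1 has all indices of that cell = 1
    for sol in sols:
        for (k, t), num in sol.num_parts.items():
            if num / sol.den_parts[(k, t)] >= 1 - 1e-9:
                cell = table[(table["dmu"] == sol.dmu) & (table["period"] == t)
                             & (table["division"] == k)]
                assert np.allclose(cell["index"], 1.0, atol=1e-6)


def test_indices_lie_in_unit_interval_iff_slack_zero():
    panel = generate_planted_frontier(8, 2, n_efficient=3, seed=6)
    sols = solve_all(panel.spec, panel.data)
    table = tabulate_indices(sols, panel.spec)
    assert ((table["index"] > 0) & (table["index"] <= 1 + 1e-9)).all()
    slack_of = {
        (s.dmu, k, t, v): (val, s.observed[(fam, k, t, v)])
        for s in sols
        for (fam, k, t, v), val in s.slacks.items()
    }
    for row in table.itertuples(index=False):
        slack, observed = slack_of[(row.dmu, row.division, row.period, row.variable)]
        assert (row.index >= 1 - 1e-9) == (slack <= 1e-9 * max(observed, 1.0) + 1e-12)


def test_index_invariance_under_column_rescaling():
    panel = generate_planted_frontier(6, 1, n_efficient=2, seed=9)
    base = tabulate_indices(solve_all(panel.spec, panel.data), panel.spec)
    division, variable = "process", "capital"
    scaled_data = validate_dataset(panel.spec, panel.data.scaled(division, variable, 41.0))
    scaled = tabulate_indices(solve_all(panel.spec, scaled_data), panel.spec)
    assert np.allclose(base["index"], scaled["index"], atol=1e-7)


def test_tabulated_layout_and_pivot_shape():
    panel = generate_planted_frontier(7, 3, n_efficient=2, seed=4)
    table = tabulate_indices(solve_all(panel.spec, panel.data), panel.spec)
    n_vars = len(panel.spec.storage_cells())
    assert len(table) == 7 * 3 * n_vars
    assert set(table.columns) == {
        "dmu", "period", "division", "variable", "role", "index", "extension"
    }
    assert table[table["role"] == "carryover"]["extension"].all()
    wide = pivot_indices(table)
    assert wide.shape == (7, n_vars * 3)
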