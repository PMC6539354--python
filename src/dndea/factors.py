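"""Per-variable total-factor efficiency indices.

Each index compares a variable's slack-adjusted target value with its
actual value for one (dmu, period):

* inputs and incoming links:  (actual - slack) / actual   (target/actual)
* good outputs:               actual / (actual + slack)   (actual/target)
* bad outputs:                (actual - slack) / actual   (target/actual)

An index of one means zero slack (that variable is at its benchmark);
values below one quantify excess input / undesirable output or desirable
output shortfall.  Indices for link variables and carry-overs are computed
the same way but flagged as extensions: links enter the receiving stage as
inputs, carry-overs as good stocks.
"""

from __future__ import annotations

import pandas as pd

from .engine import (
    FAMILY_BAD,
    FAMILY_CARRY,
    FAMILY_GOOD,
    FAMILY_INPUT,
    FAMILY_LINK,
    SlackSolution,
)
from .exceptions import DomainError, InconsistencyError
from .spec import ModelSpec, validate_spec

#: slack below this (relative to actual) counts as zero
SLACK_TOL = 1e-9


def input_factor_index(actual: float, slack: float, tol: float = SLACK_TOL) -> float:
    """Target/actual ratio for an input (or incoming link) variable."""
    if actual <= 0:
        raise DomainError(f"actual value must be positive, got {actual}")
    if slack < -tol * max(actual, 1.0):
        raise DomainError(f"negative slack {slack}")
    if slack > actual * (1 + tol):
        raise InconsistencyError(
            f"input slack {slack} exceeds actual value {actual} (solver artifact)"
        )
    return max(actual - max(slack, 0.0), 0.0) / actual


def good_output_factor_index(actual: float, slack: float, tol: float = SLACK_TOL) -> float:
    """Actual/target ratio for a desirable output variable."""
    if actual <= 0:
        raise DomainError(f"actual value must be positive, got {actual}")
    if slack < -tol * max(actual, 1.0):
        raise DomainError(f"negative slack {slack}")
    return actual / (actual + max(slack, 0.0))


def bad_output_factor_index(actual: float, slack: float, tol: float = SLACK_TOL) -> float:
    """Target/actual ratio for an undesirable output variable."""
    if actual <= 0:
        raise DomainError(f"actual value must be positive, got {actual}")
    if slack < -tol * max(actual, 1.0):
        raise DomainError(f"negative slack {slack}")
    if slack > actual * (1 + tol):
        raise InconsistencyError(
            f"bad-output slack {slack} exceeds actual value {actual} (solver artifact)"
        )
    return max(actual - max(slack, 0.0), 0.0) / actual


_FORMULA = {
    FAMILY_INPUT: input_factor_index,
    FAMILY_LINK: input_factor_index,
    FAMILY_BAD: bad_output_factor_index,
    FAMILY_GOOD: good_output_factor_index,
    FAMILY_CARRY: good_output_factor_index,
}

#: families whose indices are extensions beyond the classical per-variable set
_EXTENSION_FAMILIES = {FAMILY_LINK, FAMILY_CARRY}


def tabulate_indices(
    solutions: list[SlackSolution], spec: ModelSpec
) -> pd.DataFrame:
    """Factor-index table: one row per (dmu, period, variable).

    Requires solutions from the lexicographic slack pass so the table is
    deterministic among alternate optima.  Columns: dmu, period, division,
    variable, role, index, extension.
    """
    spec = validate_spec(spec)
    rows = []
    for sol in solutions:
        if sol.status == "failed":
            continue
        for (family, division, period, variable), slack in sol.slacks.items():
            actual = sol.observed[(family, division, period, variable)]
            index = _FORMULA[family](actual, slack)
            rows.append(
                {
                    "dmu": sol.dmu,
                    "period": period,
                    "division": division,
                    "variable": variable,
                    "role": family,
                    "index": index,
                    "extension": family in _EXTENSION_FAMILIES,
                }
            )
    if not rows:
        raise ValueError("no successfully solved DMUs to tabulate")
    table = pd.DataFrame(rows)
    order = {v: i for i, (d, v, r) in enumerate(_declared_order(spec))}
    table["_v"] = table["variable"].map(order)
    table = table.sort_values(["dmu", "period", "_v"], kind="stable").drop(columns="_v")
    return table.reset_index(drop=True)


def pivot_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Wide layout: rows dmu, columns (variable, period)."""
    wide = table.pivot_table(
        index="dmu", columns=["variable", "period"], values="index", sort=False
    )
    return wide


def _declared_order(spec: ModelSpec) -> list[tuple[str, str, str]]:
    return spec.storage_cells()
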