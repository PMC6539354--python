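import pandas as pd
import pytest

from dndea import (
    DivisionVariables,
    ModelSpec,
    PanelDataset,
    validate_dataset,
    validate_spec,
)


def long_panel(rows):
    return PanelDataset(pd.DataFrame.from_records(rows))


def single_division_rows(records, periods=("t1",)):
    """records: dict dmu -> dict var -> value or per-period list; role map inferred."""
    rows = []
    for dmu, varmap in records.items():
        for (var, role), vals in varmap.items():
            vals = vals if isinstance(vals, (list, tuple)) else [vals] * len(periods)
            for t, v in zip(periods, vals):
                rows.append(
                    dict(dmu=dmu, period=t, division="d", variable=var,
                         role=role, value=float(v))
                )
    return rows


@pytest.fixture(scope="session")
def toy_a():
    """One input, one good output; B uses twice A's input for the same output."""
    spec = validate_spec(
        ModelSpec(divisions=["d"],
                  variables={"d": DivisionVariables(inputs=["x"], good_outputs=["y"])})
    )
    rows = single_division_rows(
        {"A": {("x", "input"): 1.0, ("y", "good_output"): 1.0},
         "B": {("x", "input"): 2.0, ("y", "good_output"): 1.0}}
    )
    data = validate_dataset(spec, long_panel(rows))
    return spec, data


@pytest.fixture(scope="session")
def toy_b():
    """Adds an undesirable output; B emits twice A's bad output."""
    spec = validate_spec(
        ModelSpec(divisions=["d"],
                  variables={"d": DivisionVariables(
                      inputs=["x"], good_outputs=["y"], bad_outputs=["b"])})
    )
    rows = single_division_rows(
        {"A": {("x", "input"): 1.0, ("y", "good_output"): 1.0, ("b", "bad_output"): 1.0},
         "B": {("x", "input"): 1.0, ("y", "good_output"): 1.0, ("b", "bad_output"): 2.0}}
    )
    data = validate_dataset(spec, long_panel(rows))
    return spec, data


@pytest.fixture(scope="session")
def minimal_spec():
    return validate_spec(
        ModelSpec(divisions=["d"],
                  variables={"d": DivisionVariables(inputs=["x"], good_outputs=["y"])})
    )
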