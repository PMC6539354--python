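"""Packaged two-stage energy/health model configuration.

Stage 1 ("production") turns labor and energy consumption into GDP and
emits CO2 and an air-quality index (AQI) that flow as link variables into
stage 2 ("health_treatment"), where health expenditure and media reports
are spent to sustain the birth rate while limiting respiratory disease
and mortality (undesirable outputs).  Fixed-asset investment is the good
carry-over connecting consecutive periods; it attaches to the production
stage by default, with an option to attach it to the treatment stage
instead since capital stock can plausibly serve either side.

Units are metadata only (persons, tonnes, 100 million CNY, index points);
the efficiency scores are invariant to units of measurement.
"""

from __future__ import annotations

from typing import Optional

from .model import DEAResults, DynamicNetworkSBM
from .panel import PanelDataset
from .spec import Carryover, DivisionVariables, Link, ModelSpec, validate_spec

PRODUCTION = "production"
HEALTH = "health_treatment"

#: descriptive units for the preset variables (not used in computation)
VARIABLE_UNITS = {
    "labor": "person",
    "energy_consumption": "100 million tonnes",
    "gdp": "100 million CNY",
    "co2": "tonnes",
    "aqi": "index",
    "health_expenditure": "100 million CNY",
    "media_reports": "stories/year",
    "birth_rate": "per 1000",
    "respiratory_diseases": "person",
    "mortality_rate": "per 1000",
    "fixed_assets": "100 million CNY",
}


def build_two_stage_spec(
    carryover_division: int = 1,
    periods: Optional[list[str]] = None,
) -> ModelSpec:
    """The two-stage production/health-treatment model spec.

    Parameters
    ----------
    carryover_division
        1 (default) attaches the fixed-assets carry-over to the production
        stage; 2 attaches it to the health-treatment stage.
    periods
        Optional explicit period labels (e.g. years).
    """
    if carryover_division not in (1, 2):
        raise ValueError("carryover_division must be 1 or 2")
    carry_div = PRODUCTION if carryover_division == 1 else HEALTH
    spec = ModelSpec(
        divisions=[PRODUCTION, HEALTH],
        variables={
            PRODUCTION: DivisionVariables(
                inputs=["labor", "energy_consumption"],
                good_outputs=["gdp"],
            ),
            HEALTH: DivisionVariables(
                inputs=["health_expenditure", "media_reports"],
                good_outputs=["birth_rate"],
                bad_outputs=["respiratory_diseases", "mortality_rate"],
            ),
        },
        links=[
            Link(source=PRODUCTION, target=HEALTH, variable="co2"),
            Link(source=PRODUCTION, target=HEALTH, variable="aqi"),
        ],
        carryovers=[Carryover(division=carry_div, variable="fixed_assets")],
        periods=periods,
    )
    return validate_spec(spec)


def run_two_stage(
    data: PanelDataset,
    *,
    carryover_division: int = 1,
    link_continuity: bool = False,
    reoptimize_decompositions: bool = False,
    solver_options: Optional[dict] = None,
) -> DEAResults:
    """End-to-end driver: validate, solve all DMUs, decompose, tabulate."""
    spec = build_two_stage_spec(carryover_division=carryover_division)
    model = DynamicNetworkSBM(
        spec,
        data,
        link_continuity=link_continuity,
        reoptimize_decompositions=reoptimize_decompositions,
        solver_options=solver_options,
    )
    return model.fit()
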