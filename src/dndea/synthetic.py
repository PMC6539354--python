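"""Synthetic panels with known efficient frontiers.

Two generators:

``generate_planted_frontier``
    Draws ``n_efficient`` frontier units whose variable profiles lie, in
    every (division, period) block, on a common hyperplane with a strictly
    positive normal (positive coefficients on inputs/links/bad outputs,
    negative on good outputs/carry-overs).  Any convex combination of such
    units stays on the hyperplane, and no point of their convex hull can
    weakly dominate another (domination strictly decreases the hyperplane
    functional), so every frontier unit - and every exact convex
    combination of them - is SBM-efficient by construction.  Dominated
    units are convex combinations with all inputs/links/bad outputs
    inflated by factors > 1 and all good outputs/carry-overs deflated by
    factors < 1, which leaves a feasible benchmark (the combination
    itself, with the same weights in every intensity block, so carry-over
    continuity holds) with strictly positive slack in every variable.

``generate_two_stage_panel``
    The same planted-frontier mechanics on the packaged two-stage
    energy/health configuration, with yearbook-like structure on the
    frontier (GDP rising in labor and energy, CO2/AQI rising in energy,
    independent health expenditure and media draws, smooth fixed-asset
    stocks) and per-stage inefficiency dispersion.  The default stage-2
    dispersion is three times the stage-1 dispersion, which plants the
    qualitative property that cross-DMU spread of treatment-stage scores
    exceeds that of production-stage scores.

All randomness flows from one integer seed through a single generator in
documented order: frontier values, then combination weights, then
inflation/deflation factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import GenerationError
from .panel import PanelDataset, validate_dataset
from .spec import (
    Carryover,
    DivisionVariables,
    ModelSpec,
    ROLE_BAD,
    ROLE_CARRY,
    ROLE_GOOD,
    ROLE_INPUT,
    ROLE_LINK,
    validate_spec,
)
from .two_stage import HEALTH, PRODUCTION, build_two_stage_spec

#: log10 span of frontier magnitudes (two decades exercises units-invariance)
MAGNITUDE_DECADES = 2.0

#: roles whose slack direction is "less is better" for the benchmark
_BAD_DIR = {ROLE_INPUT, ROLE_LINK, ROLE_BAD}
_GOOD_DIR = {ROLE_GOOD, ROLE_CARRY}


@dataclass
class SyntheticPanel:
    """A generated panel plus its planted structure.

    ``certificates`` maps each dominated DMU to the convex weights over
    the planted units and the per-variable inflation/deflation factors
    used to build it, so tests can verify the domination arithmetic
    without running any solver.
    """

    data: PanelDataset
    spec: ModelSpec
    planted_efficient_ids: list[str]
    certificates: dict[str, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)


def default_frontier_spec() -> ModelSpec:
    """Small single-division dynamic spec used for frontier studies."""
    return validate_spec(
        ModelSpec(
            divisions=["process"],
            variables={
                "process": DivisionVariables(
                    inputs=["capital", "labor"],
                    good_outputs=["output"],
                    bad_outputs=["waste"],
                )
            },
            carryovers=[Carryover(division="process", variable="stock")],
        )
    )


def _block_cells(spec: ModelSpec, division: str) -> list[tuple[str, str, str]]:
    """(storage_division, variable, role) cells constraining one division's
    intensity block: own inputs/outputs, incoming links, own carry-overs."""
    dv = spec.division_variables(division)
    cells = [(division, v, ROLE_INPUT) for v in dv.inputs]
    cells += [(division, v, ROLE_GOOD) for v in dv.good_outputs]
    cells += [(division, v, ROLE_BAD) for v in dv.bad_outputs]
    cells += [(l.source, l.variable, ROLE_LINK) for l in spec.links_into(division)]
    cells += [(division, c.variable, ROLE_CARRY) for c in spec.carryovers_of(division)]
    return cells


def _project_to_hyperplane(
    values: dict[tuple[str, str], np.ndarray],
    cells: list[tuple[str, str, str]],
    rng: np.random.Generator,
) -> None:
    """Resolve one good-direction variable per block so all units lie on a
    common positive-normal hyperplane; mutates ``values`` in place.

    The hyperplane is sum(alpha_v * bad_dir) - sum(beta_v * good_dir) = c
    with alpha, beta > 0; the resolved variable's column is computed from
    the others, with the offset c chosen so the column stays positive.
    """
    good_cells = [cell for cell in cells if cell[2] in _GOOD_DIR]
    bad_cells = [cell for cell in cells if cell[2] in _BAD_DIR]
    if not good_cells:
        raise GenerationError(
            "planted frontier needs at least one good output or carry-over per division"
        )
    resolve = good_cells[0]
    others_good = good_cells[1:]
    # positive normal, scaled to each variable's magnitude so terms are O(1)
    lhs = np.zeros_like(values[(resolve[0], resolve[1])])
    for div, var, _role in bad_cells:
        col = values[(div, var)]
        alpha = rng.uniform(0.5, 1.5) / col.mean()
        lhs = lhs + alpha * col
    for div, var, _role in others_good:
        col = values[(div, var)]
        beta = rng.uniform(0.2, 0.5) / col.mean()
        lhs = lhs - beta * col
    # choose offset so the resolved column is strictly positive with spread
    c = lhs.min() - rng.uniform(0.3, 0.7) * (np.ptp(lhs) + 1.0)
    resolved = lhs - c
    target_scale = 10 ** rng.uniform(0.5, MAGNITUDE_DECADES)
    values[(resolve[0], resolve[1])] = resolved / resolved.mean() * target_scale


def generate_planted_frontier(
    n_dmu: int,
    n_periods: int,
    spec: Optional[ModelSpec] = None,
    n_efficient: int = 3,
    seed: int = 0,
    *,
    inflation: tuple[float, float] = (1.05, 1.5),
    deflation: tuple[float, float] = (0.6, 0.95),
) -> SyntheticPanel:
    """Panel with ``n_efficient`` planted efficient units.

    Every non-planted unit is a convex combination of the planted units
    (same weights in every division-period block) with inflated
    inputs/links/bad outputs and deflated good outputs/carry-overs, hence
    weakly dominated in every block and strictly inefficient whenever the
    factors are not all one.  Setting both factor ranges to (1, 1) makes
    every unit an exact frontier combination, hence efficient.
    """
    spec = validate_spec(spec if spec is not None else default_frontier_spec())
    if not 1 <= n_efficient <= n_dmu:
        raise GenerationError(f"need 1 <= n_efficient={n_efficient} <= n_dmu={n_dmu}")
    if n_periods < 1:
        raise GenerationError("n_periods must be >= 1")
    rng = np.random.default_rng(seed)
    periods = (
        list(spec.periods)
        if spec.periods is not None
        else [f"t{i + 1}" for i in range(n_periods)]
    )
    if len(periods) != n_periods:
        raise GenerationError(
            f"spec declares {len(periods)} periods but n_periods={n_periods}"
        )

    eff_ids = [f"E{i + 1:02d}" for i in range(n_efficient)]
    dom_ids = [f"U{i + 1:02d}" for i in range(n_dmu - n_efficient)]

    # 1. frontier values: log-uniform draws, carry-overs smoothed over time,
    #    then per-block hyperplane projection
    frontier: dict[tuple[str, str, str], np.ndarray] = {}  # (div, var, t) -> [n_eff]
    carry_names = {(c.division, c.variable) for c in spec.carryovers}
    for division, variable, _role in spec.storage_cells():
        base = 10 ** rng.uniform(0.0, MAGNITUDE_DECADES, size=n_efficient)
        for ti, t in enumerate(periods):
            if (division, variable) in carry_names and ti > 0:
                drift = np.exp(rng.uniform(-0.1, 0.1, size=n_efficient))
                base = frontier[(division, variable, periods[ti - 1])] * drift
            frontier[(division, variable, t)] = base.copy()
    for division in spec.divisions:
        cells = _block_cells(spec, division)
        for t in periods:
            block = {(d, v): frontier[(d, v, t)] for d, v, _r in cells}
            _project_to_hyperplane(block, cells, rng)
            for (d, v), col in block.items():
                frontier[(d, v, t)] = col

    # 2. combination weights for dominated units
    weights = {
        dmu: rng.dirichlet(np.ones(n_efficient)) for dmu in dom_ids
    }

    # 3. inflation/deflation factors per (dominated unit, cell, period)
    records = []
    certificates: dict[str, dict] = {}
    role_of = {(d, v): r for d, v, r in spec.storage_cells()}
    for i, dmu in enumerate(eff_ids):
        for (division, variable, t), col in frontier.items():
            records.append(
                dict(
                    dmu=dmu,
                    period=t,
                    division=division,
                    variable=variable,
                    role=role_of[(division, variable)],
                    value=float(col[i]),
                )
            )
    for dmu in dom_ids:
        w = weights[dmu]
        factors: dict[tuple[str, str, str], float] = {}
        for (division, variable, t), col in frontier.items():
            combo = float(w @ col)
            role = role_of[(division, variable)]
            if role in _BAD_DIR:
                f = float(rng.uniform(*inflation))
            else:
                f = float(rng.uniform(*deflation))
            factors[(division, variable, t)] = f
            records.append(
                dict(
                    dmu=dmu,
                    period=t,
                    division=division,
                    variable=variable,
                    role=role,
                    value=combo * f,
                )
            )
        certificates[dmu] = {
            "weights": {e: float(v) for e, v in zip(eff_ids, w)},
            "factors": {"|".join(k): v for k, v in factors.items()},
        }

    frame = pd.DataFrame.from_records(records)
    data = validate_dataset(spec, PanelDataset(frame, eff_ids + dom_ids, periods))
    return SyntheticPanel(
        data=data,
        spec=spec,
        planted_efficient_ids=eff_ids,
        certificates=certificates,
        params=dict(
            n_dmu=n_dmu,
            n_periods=n_periods,
            n_efficient=n_efficient,
            seed=seed,
            inflation=inflation,
            deflation=deflation,
        ),
        provenance=[
            "frontier values drawn log-uniform over "
            f"{MAGNITUDE_DECADES} decades and projected onto per-block "
            "positive-normal hyperplanes",
            "dominated units are convex combinations with inflated "
            "inputs/links/bads and deflated goods/carry-overs",
        ],
    )


def generate_two_stage_panel(
    n_dmu: int = 31,
    n_periods: int = 4,
    stage1_dispersion: float = 0.15,
    stage2_dispersion: float = 0.45,
    seed: int = 0,
    carryover_division: int = 1,
) -> SyntheticPanel:
    """Yearbook-like two-stage panel (default 31 cities x 4 years).

    Frontier units carry the structural correlations of city statistics -
    GDP increasing in labor and energy, CO2 and AQI increasing in energy,
    health expenditure and media reports independent, undesirable health
    outputs increasing in the pollution links - and dominated units apply
    per-stage multiplicative inefficiency: |N(0, dispersion_s)| in the log
    of each stage-s variable.  A larger ``stage2_dispersion`` spreads the
    treatment-stage scores more than the production-stage scores.
    """
    if stage1_dispersion <= 0 or stage2_dispersion <= 0:
        raise GenerationError("dispersion parameters must be positive")
    spec = build_two_stage_spec(carryover_division=carryover_division)
    rng = np.random.default_rng(seed)
    n_eff = max(2, int(round(n_dmu / 8)))
    if n_eff >= n_dmu:
        n_eff = max(1, n_dmu - 1)
    periods = [str(2013 + i) for i in range(n_periods)]
    eff_ids = [f"E{i + 1:02d}" for i in range(n_eff)]
    dom_ids = [f"U{i + 1:02d}" for i in range(n_dmu - n_eff)]

    # stage membership of each stored variable, for dispersion assignment:
    # link variables are consumed by (and their slack scored in) stage 2
    stage_of = {
        "labor": 1, "energy_consumption": 1, "gdp": 1,
        "co2": 2, "aqi": 2,
        "health_expenditure": 2, "media_reports": 2, "birth_rate": 2,
        "respiratory_diseases": 2, "mortality_rate": 2,
        "fixed_assets": carryover_division,
    }
    dispersion = {1: stage1_dispersion, 2: stage2_dispersion}

    # 1. structural frontier draws (per period; smooth stocks)
    frontier: dict[tuple[str, str, str], np.ndarray] = {}
    labor = 10 ** rng.uniform(0.5, 2.0, n_eff)
    energy = 10 ** rng.uniform(0.5, 2.0, n_eff)
    health = 10 ** rng.uniform(0.5, 2.0, n_eff)
    media = 10 ** rng.uniform(0.5, 2.0, n_eff)
    assets = 10 ** rng.uniform(0.5, 2.0, n_eff)
    carry_div = PRODUCTION if carryover_division == 1 else HEALTH
    for ti, t in enumerate(periods):
        grow = np.exp(rng.normal(0.02, 0.02, n_eff)) if ti else np.ones(n_eff)
        labor, energy = labor * grow, energy * grow
        health, media = health * grow, media * grow
        assets = assets * np.exp(rng.normal(0.03, 0.02, n_eff)) if ti else assets
        co2 = 0.8 * energy ** 0.9 * np.exp(rng.normal(0, 0.05, n_eff))
        aqi = 30.0 * (energy / energy.mean()) ** 0.5 * np.exp(rng.normal(0, 0.05, n_eff))
        resp = 0.5 * co2 ** 0.8 * np.exp(rng.normal(0, 0.05, n_eff))
        mort = 0.2 * aqi ** 0.7 * np.exp(rng.normal(0, 0.05, n_eff))
        gdp = labor ** 0.4 * energy ** 0.6 * np.exp(rng.normal(0, 0.05, n_eff))
        birth = np.full(n_eff, 10.0)  # resolved onto the stage-2 hyperplane below
        frontier[(PRODUCTION, "labor", t)] = labor.copy()
        frontier[(PRODUCTION, "energy_consumption", t)] = energy.copy()
        frontier[(PRODUCTION, "gdp", t)] = gdp
        frontier[(PRODUCTION, "co2", t)] = co2
        frontier[(PRODUCTION, "aqi", t)] = aqi
        frontier[(HEALTH, "health_expenditure", t)] = health.copy()
        frontier[(HEALTH, "media_reports", t)] = media.copy()
        frontier[(HEALTH, "birth_rate", t)] = birth
        frontier[(HEALTH, "respiratory_diseases", t)] = resp
        frontier[(HEALTH, "mortality_rate", t)] = mort
        frontier[(carry_div, "fixed_assets", t)] = assets.copy()
    # project each block onto its hyperplane (resolves gdp resp. birth_rate,
    # the first good-direction cell of each block)
    for division in spec.divisions:
        cells = _block_cells(spec, division)
        for t in periods:
            block = {(d, v): frontier[(d, v, t)] for d, v, _r in cells}
            _project_to_hyperplane(block, cells, rng)
            for (d, v), col in block.items():
                frontier[(d, v, t)] = col

    # 2. combination weights, 3. per-stage inefficiency factors
    role_of = {(d, v): r for d, v, r in spec.storage_cells()}
    records = []
    certificates: dict[str, dict] = {}
    for i, dmu in enumerate(eff_ids):
        for (division, variable, t), col in frontier.items():
            records.append(
                dict(dmu=dmu, period=t, division=division, variable=variable,
                     role=role_of[(division, variable)], value=float(col[i]))
            )
    for dmu in dom_ids:
        w = rng.dirichlet(np.ones(n_eff))
        # one inefficiency level per (unit, stage), spread across variables
        level = {s: abs(rng.normal(0.0, dispersion[s])) for s in (1, 2)}
        factors: dict[tuple[str, str, str], float] = {}
        for (division, variable, t), col in frontier.items():
            combo = float(w @ col)
            u = level[stage_of[variable]] * np.exp(rng.normal(0, 0.1))
            role = role_of[(division, variable)]
            f = float(np.exp(u)) if role in _BAD_DIR else float(np.exp(-u))
            factors[(division, variable, t)] = f
            records.append(
                dict(dmu=dmu, period=t, division=division, variable=variable,
                     role=role, value=combo * f)
            )
        certificates[dmu] = {
            "weights": {e: float(v) for e, v in zip(eff_ids, w)},
            "factors": {"|".join(k): v for k, v in factors.items()},
        }

    frame = pd.DataFrame.from_records(records)
    data = validate_dataset(spec, PanelDataset(frame, eff_ids + dom_ids, periods))
    return SyntheticPanel(
        data=data,
        spec=spec,
        planted_efficient_ids=eff_ids,
        certificates=certificates,
        params=dict(
            n_dmu=n_dmu, n_periods=n_periods, seed=seed,
            stage1_dispersion=stage1_dispersion,
            stage2_dispersion=stage2_dispersion,
            carryover_division=carryover_division,
        ),
        provenance=[
            "two-stage yearbook-like panel with planted hyperplane frontier",
            f"stage dispersions: {stage1_dispersion} (production), "
            f"{stage2_dispersion} (health treatment)",
        ],
    )


def generate_small_instance(seed: int) -> tuple[ModelSpec, PanelDataset, str]:
    """Random tiny instance (n <= 3, K = 1, T <= 2) for oracle comparisons.

    Returns (spec, data, dmu): the instance plus one DMU to evaluate.
    Carry-overs are drawn only when the grid reference minimizer can
    enforce their continuity constraint exactly (T = 1, or n <= 2).
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 4))
    t_count = int(rng.integers(1, 3))
    m = int(rng.integers(1, 3))
    r2 = int(rng.integers(0, 2))
    with_carry = bool(rng.integers(0, 2)) and (t_count == 1 or n <= 2)
    dv = DivisionVariables(
        inputs=[f"x{i}" for i in range(m)],
        good_outputs=["y"],
        bad_outputs=["b"] if r2 else [],
    )
    spec = ModelSpec(
        divisions=["d"],
        variables={"d": dv},
        carryovers=[Carryover(division="d", variable="z")] if with_carry else [],
    )
    spec = validate_spec(spec)
    periods = [f"t{i + 1}" for i in range(t_count)]
    dmus = [f"dmu{i + 1}" for i in range(n)]
    records = []
    for division, variable, role in spec.storage_cells():
        for t in periods:
            vals = 10 ** rng.uniform(0.0, MAGNITUDE_DECADES, n)
            for dmu, v in zip(dmus, vals):
                records.append(
                    dict(dmu=dmu, period=t, division=division,
                         variable=variable, role=role, value=float(v))
                )
    data = validate_dataset(spec, PanelDataset(pd.DataFrame.from_records(records), dmus, periods))
    dmu = dmus[int(rng.integers(0, n))]
    return spec, data, dmu
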