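"""Fractional SBM program assembly, Charnes-Cooper linearization and solving.

For each evaluated DMU *o* the non-oriented dynamic network SBM is a ratio
program: the numerator averages, over periods t and divisions k with
weights W^t W^k, the terms

    N_k^t = 1 - (1/(m_k + linkin_k)) * (sum_i s_i^-/x_oi + sum_l s_l^in/z_ol)

and the denominator averages

    D_k^t = 1 + (1/(r1_k + r2_k + ngood_k)) *
            (sum_r s_r^good+/y_or + sum_r s_r^bad-/y_or^bad + sum_c s_c^carry/z_oc)

subject to, for every (k, t): input, good-output, bad-output, incoming-link
and carry-over balance equations against the convex intensity vector
lambda_k^t (e lambda = 1, variable returns to scale), plus carry-over
continuity between consecutive periods.  The ratio is minimized.

The program is linear-fractional, so the Charnes-Cooper substitution
(Lambda, S, tau) = tau * (lambda, s, 1) with the denominator pinned to 1
turns it into an LP solved here with HiGHS (`scipy.optimize.linprog`).
A second, lexicographic solve maximizes the total slack-to-observation sum
at the optimal ratio so reported slacks (and the factor indices derived
from them) are deterministic among alternate optima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linprog

from .exceptions import LinearizationError, SolverError
from .panel import PanelDataset, validate_dataset
from .spec import ModelSpec, validate_spec

logger = logging.getLogger(__name__)

#: families of slack variables; numerator families first
FAMILY_INPUT = "input"
FAMILY_LINK = "link_in"
FAMILY_GOOD = "good_output"
FAMILY_BAD = "bad_output"
FAMILY_CARRY = "carryover"

NUMERATOR_FAMILIES = (FAMILY_INPUT, FAMILY_LINK)
DENOMINATOR_FAMILIES = (FAMILY_GOOD, FAMILY_BAD, FAMILY_CARRY)

TAU_MIN = 1e-9
RESIDUAL_TOL = 1e-6


@dataclass
class FractionalProgram:
    """The assembled ratio program for one evaluated DMU.

    Decision variables are indexed 0..n_vars-1: first the intensity blocks
    lambda_k^t (one length-n block per division-period), then one slack per
    (family, division, period, variable).  ``bracket_num``/``bracket_den``
    hold the affine bracket terms N_k^t and D_k^t as constant 1 plus a
    sparse coefficient map over the slack indices; ``weight`` carries the
    W^t W^k factor each bracket receives in the overall objective.
    """

    spec: ModelSpec
    data: PanelDataset
    dmu: str
    link_continuity: bool
    n_vars: int
    lam_idx: dict[tuple[str, str], np.ndarray]
    slack_idx: dict[tuple[str, str, str, str], int]
    slack_obs: dict[int, float]
    bracket_num: dict[tuple[str, str], dict[int, float]]
    bracket_den: dict[tuple[str, str], dict[int, float]]
    weight: dict[tuple[str, str], float]
    period_weights: dict[str, float]
    division_weights: dict[str, float]
    rows: list[tuple[dict[int, float], float, str]] = field(default_factory=list)


@dataclass
class LinearProgram:
    """Charnes-Cooper linearization of a :class:`FractionalProgram`.

    The scaled variables are [V, tau] with V = tau * (lambda, s); every
    fractional equality row ``a.v = b`` becomes ``a.V - b*tau = 0`` and the
    denominator is pinned to one.  Recovering (lambda, s) = V/tau from any
    feasible LP point yields a feasible fractional point with the same
    objective ratio, so the LP minimum equals the fractional minimum.
    """

    fp: FractionalProgram
    c: np.ndarray
    a_eq: np.ndarray
    b_eq: np.ndarray
    bounds: list[tuple[float, Optional[float]]]
    tau_index: int
    num_vec: np.ndarray
    den_vec: np.ndarray
    slack_ratio_vec: np.ndarray


@dataclass
class SlackSolution:
    """Optimal slacks, intensities and bracket values for one DMU."""

    dmu: str
    theta: float
    status: str
    lam: dict[tuple[str, str], np.ndarray]
    slacks: dict[tuple[str, str, str, str], float]
    observed: dict[tuple[str, str, str, str], float]
    num_parts: dict[tuple[str, str], float]
    den_parts: dict[tuple[str, str], float]
    period_weights: dict[str, float]
    division_weights: dict[str, float]
    residuals: dict[str, float]
    link_continuity: bool = False

    @property
    def periods(self) -> list[str]:
        return list(self.period_weights)

    @property
    def divisions(self) -> list[str]:
        return list(self.division_weights)

    def slack(self, family: str, division: str, period: str, variable: str) -> float:
        return self.slacks[(family, division, period, variable)]

    def max_residual(self) -> float:
        return max(self.residuals.values(), default=0.0)

    def is_efficient(self, tol: float = RESIDUAL_TOL) -> bool:
        return self.theta >= 1.0 - tol


def assemble_program(
    spec: ModelSpec,
    data: PanelDataset,
    dmu: str,
    link_continuity: bool = False,
) -> FractionalProgram:
    """Build the ratio program of one DMU from a validated spec and panel."""
    spec = validate_spec(spec)
    if not data.validated:
        data = validate_dataset(spec, data)
    if dmu not in data.dmu_ids:
        raise KeyError(f"unknown DMU {dmu!r}")
    o = data.dmu_ids.index(dmu)
    periods = data.periods
    divisions = spec.divisions
    n = data.n_dmu

    wt = spec.weights.resolved_period_weights(len(periods))
    wk = spec.weights.resolved_division_weights(len(divisions))
    period_weights = {t: float(w) for t, w in zip(periods, wt)}
    division_weights = {k: float(w) for k, w in zip(divisions, wk)}

    lam_idx: dict[tuple[str, str], np.ndarray] = {}
    cursor = 0
    for k in divisions:
        for t in periods:
            lam_idx[(k, t)] = np.arange(cursor, cursor + n)
            cursor += n

    slack_idx: dict[tuple[str, str, str, str], int] = {}
    slack_obs: dict[int, float] = {}

    def new_slack(family: str, k: str, t: str, var: str, obs: float) -> int:
        nonlocal cursor
        idx = cursor
        slack_idx[(family, k, t, var)] = idx
        slack_obs[idx] = obs
        cursor += 1
        return idx

    bracket_num: dict[tuple[str, str], dict[int, float]] = {}
    bracket_den: dict[tuple[str, str], dict[int, float]] = {}
    weight: dict[tuple[str, str], float] = {}
    rows: list[tuple[dict[int, float], float, str]] = []

    for k in divisions:
        dv = spec.division_variables(k)
        links_in = spec.links_into(k)
        carries = spec.carryovers_of(k)
        dims = spec.dims(k)
        num_norm = 1.0 / (dims.m + dims.linkin) if (dims.m + dims.linkin) else 0.0
        den_norm = (
            1.0 / (dims.r1 + dims.r2 + dims.ngood)
            if (dims.r1 + dims.r2 + dims.ngood)
            else 0.0
        )
        for t in periods:
            lam = lam_idx[(k, t)]
            ncoef: dict[int, float] = {}
            dcoef: dict[int, float] = {}
            # inputs: x_o = X lambda + s-
            for var in dv.inputs:
                col = data.column(k, var, t)
                s = new_slack(FAMILY_INPUT, k, t, var, col[o])
                rows.append((_row(lam, col, {s: 1.0}), col[o], FAMILY_INPUT))
                ncoef[s] = -num_norm / col[o]
            # incoming links: z_o = Z lambda_k + s_in (values stored at source)
            for link in links_in:
                col = data.column(link.source, link.variable, t)
                s = new_slack(FAMILY_LINK, k, t, link.variable, col[o])
                rows.append((_row(lam, col, {s: 1.0}), col[o], FAMILY_LINK))
                ncoef[s] = -num_norm / col[o]
            # good outputs: y_o = Y lambda - s+
            for var in dv.good_outputs:
                col = data.column(k, var, t)
                s = new_slack(FAMILY_GOOD, k, t, var, col[o])
                rows.append((_row(lam, col, {s: -1.0}), col[o], FAMILY_GOOD))
                dcoef[s] = den_norm / col[o]
            # bad outputs: y_o^bad = Y^bad lambda + s-
            for var in dv.bad_outputs:
                col = data.column(k, var, t)
                s = new_slack(FAMILY_BAD, k, t, var, col[o])
                rows.append((_row(lam, col, {s: 1.0}), col[o], FAMILY_BAD))
                dcoef[s] = den_norm / col[o]
            # good carry-overs: z_o^(t,t+1) = sum_j z_j lambda_j - s
            for carry in carries:
                col = data.column(k, carry.variable, t)
                s = new_slack(FAMILY_CARRY, k, t, carry.variable, col[o])
                rows.append((_row(lam, col, {s: -1.0}), col[o], FAMILY_CARRY))
                dcoef[s] = den_norm / col[o]
            # convexity: e lambda = 1 (variable returns to scale)
            rows.append((_row(lam, np.ones(n), {}), 1.0, "convexity"))
            bracket_num[(k, t)] = ncoef
            bracket_den[(k, t)] = dcoef
            weight[(k, t)] = period_weights[t] * division_weights[k]
    # carry-over continuity between consecutive periods
    for k in divisions:
        for carry in spec.carryovers_of(k):
            for ti in range(len(periods) - 1):
                t, t_next = periods[ti], periods[ti + 1]
                col = data.column(k, carry.variable, t)
                coefs: dict[int, float] = {}
                for j, idx in enumerate(lam_idx[(k, t)]):
                    coefs[idx] = coefs.get(idx, 0.0) + col[j]
                for j, idx in enumerate(lam_idx[(k, t_next)]):
                    coefs[idx] = coefs.get(idx, 0.0) - col[j]
                rows.append((coefs, 0.0, "continuity"))
    # optional fixed-link continuity between source and target blocks
    if link_continuity:
        for link in spec.links:
            for t in periods:
                col = data.column(link.source, link.variable, t)
                coefs = {}
                for j, idx in enumerate(lam_idx[(link.source, t)]):
                    coefs[idx] = coefs.get(idx, 0.0) + col[j]
                for j, idx in enumerate(lam_idx[(link.target, t)]):
                    coefs[idx] = coefs.get(idx, 0.0) - col[j]
                rows.append((coefs, 0.0, "link_continuity"))

    return FractionalProgram(
        spec=spec,
        data=data,
        dmu=dmu,
        link_continuity=link_continuity,
        n_vars=cursor,
        lam_idx=lam_idx,
        slack_idx=slack_idx,
        slack_obs=slack_obs,
        bracket_num=bracket_num,
        bracket_den=bracket_den,
        weight=weight,
        period_weights=period_weights,
        division_weights=division_weights,
        rows=rows,
    )


def _row(lam: np.ndarray, col: np.ndarray, extra: dict[int, float]) -> dict[int, float]:
    coefs = {int(idx): float(c) for idx, c in zip(lam, col)}
    coefs.update(extra)
    return coefs


def linearize(
    fp: FractionalProgram,
    objective_weights: Optional[dict[tuple[str, str], float]] = None,
    tau_min: float = TAU_MIN,
) -> LinearProgram:
    """Charnes-Cooper transformation of the ratio program.

    ``objective_weights`` replaces the W^t W^k weighting of the bracket
    terms (used for period/division re-optimization); the default is the
    overall objective.
    """
    w = fp.weight if objective_weights is None else objective_weights
    nv = fp.n_vars + 1
    tau = fp.n_vars

    num_vec = np.zeros(nv)
    den_vec = np.zeros(nv)
    for kt, omega in w.items():
        num_vec[tau] += omega
        den_vec[tau] += omega
        for idx, coef in fp.bracket_num[kt].items():
            num_vec[idx] += omega * coef
        for idx, coef in fp.bracket_den[kt].items():
            den_vec[idx] += omega * coef
    if not np.any(den_vec):
        raise LinearizationError("normalization row is identically zero")

    a_rows = []
    b = []
    for coefs, rhs, _tag in fp.rows:
        row = np.zeros(nv)
        for idx, coef in coefs.items():
            row[idx] += coef
        row[tau] -= rhs
        a_rows.append(row)
        b.append(0.0)
    a_rows.append(den_vec)
    b.append(1.0)

    slack_ratio_vec = np.zeros(nv)
    for idx, obs in fp.slack_obs.items():
        slack_ratio_vec[idx] = 1.0 / obs

    bounds: list[tuple[float, Optional[float]]] = [(0.0, None)] * fp.n_vars
    bounds.append((tau_min, None))
    return LinearProgram(
        fp=fp,
        c=num_vec.copy(),
        a_eq=np.vstack(a_rows),
        b_eq=np.asarray(b),
        bounds=bounds,
        tau_index=tau,
        num_vec=num_vec,
        den_vec=den_vec,
        slack_ratio_vec=slack_ratio_vec,
    )


def _linprog(c, a_eq, b_eq, bounds, solver_options=None):
    options = dict(solver_options or {})
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs", options=options)
    return res


def solve_dmu(
    spec: ModelSpec,
    data: PanelDataset,
    dmu: str,
    *,
    link_continuity: bool = False,
    lexicographic: bool = True,
    objective_weights: Optional[dict[tuple[str, str], float]] = None,
    solver_options: Optional[dict] = None,
    tol: float = RESIDUAL_TOL,
) -> SlackSolution:
    """Solve the SBM program of one DMU and return its optimal slacks.

    A first LP solve yields the optimal ratio theta; a second solve
    (``lexicographic=True``) maximizes the total slack/observation sum at
    that ratio so the reported slack profile is a deterministic extreme
    point of the optimal face.
    """
    fp = assemble_program(spec, data, dmu, link_continuity=link_continuity)
    lp = linearize(fp, objective_weights=objective_weights)
    res = _linprog(lp.c, lp.a_eq, lp.b_eq, lp.bounds, solver_options)
    if res.status != 0:
        raise SolverError(f"DMU {dmu!r}: solver status {res.status} ({res.message})")
    theta = float(res.fun)
    x = np.asarray(res.x)
    status = "optimal"

    if lexicographic:
        a2 = np.vstack([lp.a_eq, lp.num_vec])
        b2 = np.append(lp.b_eq, theta)
        res2 = _linprog(-lp.slack_ratio_vec, a2, b2, lp.bounds, solver_options)
        if res2.status == 0:
            x = np.asarray(res2.x)
            status = "optimal-lexicographic"
        else:  # keep the first-stage solution; slacks may be non-extreme
            logger.warning("DMU %r: lexicographic pass failed (%s)", dmu, res2.message)
            status = "optimal-nonlex"

    tau = float(x[lp.tau_index])
    if tau <= 0:
        raise SolverError(f"DMU {dmu!r}: degenerate scaling tau={tau}")
    lam = {kt: x[idx] / tau for kt, idx in fp.lam_idx.items()}
    slacks = {
        key: max(float(x[idx]) / tau, 0.0) for key, idx in fp.slack_idx.items()
    }
    observed = {key: fp.slack_obs[idx] for key, idx in fp.slack_idx.items()}
    num_parts = {}
    den_parts = {}
    for kt in fp.weight:
        num_parts[kt] = 1.0 + sum(
            coef * (x[idx] / tau) for idx, coef in fp.bracket_num[kt].items()
        )
        den_parts[kt] = 1.0 + sum(
            coef * (x[idx] / tau) for idx, coef in fp.bracket_den[kt].items()
        )

    sol = SlackSolution(
        dmu=dmu,
        theta=theta,
        status=status,
        lam=lam,
        slacks=slacks,
        observed=observed,
        num_parts=num_parts,
        den_parts=den_parts,
        period_weights=fp.period_weights,
        division_weights=fp.division_weights,
        residuals={},
        link_continuity=link_continuity,
    )
    sol.residuals = verify_solution(sol, spec, data, tol=tol).by_family
    if sol.max_residual() > tol:
        logger.warning(
            "DMU %r: max constraint residual %.2e exceeds %.0e",
            dmu,
            sol.max_residual(),
            tol,
        )
    return sol


def solve_all(
    spec: ModelSpec,
    data: PanelDataset,
    *,
    link_continuity: bool = False,
    lexicographic: bool = True,
    solver_options: Optional[dict] = None,
) -> list[SlackSolution]:
    """Solve every DMU in deterministic (sorted dmu_id) order.

    Per-DMU solver failures are collected, logged and reported as
    solutions with status ``"failed"`` and NaN score; the batch never
    aborts on a single unit.
    """
    spec = validate_spec(spec)
    if not data.validated:
        data = validate_dataset(spec, data)
    solutions = []
    for dmu in sorted(data.dmu_ids):
        try:
            sol = solve_dmu(
                spec,
                data,
                dmu,
                link_continuity=link_continuity,
                lexicographic=lexicographic,
                solver_options=solver_options,
            )
        except SolverError as exc:
            logger.error("DMU %r failed: %s", dmu, exc)
            sol = SlackSolution(
                dmu=dmu,
                theta=float("nan"),
                status="failed",
                lam={},
                slacks={},
                observed={},
                num_parts={},
                den_parts={},
                period_weights={},
                division_weights={},
                residuals={},
                link_continuity=link_continuity,
            )
        logger.info("DMU %r: theta=%.6f status=%s", dmu, sol.theta, sol.status)
        solutions.append(sol)
    return solutions


@dataclass
class VerificationReport:
    """Maximum absolute residual of each constraint family."""

    by_family: dict[str, float]
    tol: float = RESIDUAL_TOL

    @property
    def max_residual(self) -> float:
        return max(self.by_family.values(), default=0.0)

    @property
    def passed(self) -> bool:
        return self.max_residual <= self.tol


def verify_solution(
    sol: SlackSolution,
    spec: ModelSpec,
    data: PanelDataset,
    tol: float = RESIDUAL_TOL,
) -> VerificationReport:
    """Recompute constraint residuals of a solution in the original scale."""
    fp = assemble_program(spec, data, sol.dmu, link_continuity=sol.link_continuity)
    v = np.zeros(fp.n_vars)
    for kt, idx in fp.lam_idx.items():
        v[idx] = sol.lam[kt]
    for key, idx in fp.slack_idx.items():
        v[idx] = sol.slacks[key]
    by_family: dict[str, float] = {}
    for coefs, rhs, tag in fp.rows:
        resid = abs(sum(coef * v[idx] for idx, coef in coefs.items()) - rhs)
        by_family[tag] = max(by_family.get(tag, 0.0), resid)
    return VerificationReport(by_family=by_family, tol=tol)


def restricted_score(
    spec: ModelSpec,
    data: PanelDataset,
    dmu: str,
    *,
    periods: Optional[list[str]] = None,
    divisions: Optional[list[str]] = None,
    link_continuity: bool = False,
    solver_options: Optional[dict] = None,
) -> float:
    """Re-optimized period/division/division-period score of one DMU.

    The constraint set is unchanged; only the bracket terms of the selected
    periods/divisions enter the ratio objective, with division weights W^k
    when a single period is selected, period weights W^t when a single
    division is selected, and weight one for a single (k, t) cell.
    """
    fp = assemble_program(spec, data, dmu, link_continuity=link_continuity)
    sel_p = list(fp.period_weights) if periods is None else list(periods)
    sel_k = list(fp.division_weights) if divisions is None else list(divisions)
    for t in sel_p:
        if t not in fp.period_weights:
            raise KeyError(f"unknown period {t!r}")
    for k in sel_k:
        if k not in fp.division_weights:
            raise KeyError(f"unknown division {k!r}")
    weights: dict[tuple[str, str], float] = {}
    for k in sel_k:
        for t in sel_p:
            w = 1.0
            if periods is None:
                w *= fp.period_weights[t]
            if divisions is None:
                w *= fp.division_weights[k]
            weights[(k, t)] = w
    total = sum(weights.values())
    weights = {kt: w / total for kt, w in weights.items()}
    lp = linearize(fp, objective_weights=weights)
    res = _linprog(lp.c, lp.a_eq, lp.b_eq, lp.bounds, solver_options)
    if res.status != 0:
        raise SolverError(f"DMU {dmu!r}: solver status {res.status} ({res.message})")
    return float(res.fun)
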