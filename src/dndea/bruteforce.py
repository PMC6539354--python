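"""Brute-force grid minimizer for tiny single-division instances.

This is a reference implementation used to cross-check the LP engine on
instances with at most three DMUs, one division and at most two periods.
It never touches the linear-programming path: slacks are eliminated
analytically (each balance equation determines its slack uniquely from
the intensity vector), feasibility is checked pointwise, and the ratio
objective is enumerated over a regular grid on each lambda simplex.

For two uncoupled periods the minimum of the summed ratio over the product
of the two per-period grids is found by Dinkelbach iteration *on the grid*
(each step is a pure vectorized enumeration), which is exact for the grid
without materializing the product set.  When a carry-over continuity
constraint couples the periods the instance must have at most two DMUs;
the coupling is then enforced by exact pairwise enumeration of the two
1-D grids.
"""

from __future__ import annotations

import itertools

import numpy as np

from .panel import PanelDataset, validate_dataset
from .spec import ModelSpec, validate_spec

_FEAS_TOL = 1e-9


def simplex_grid(n: int, step: float) -> np.ndarray:
    """All points of the (n-1)-simplex with coordinates on a ``step`` grid."""
    m = int(round(1.0 / step))
    if n == 1:
        return np.ones((1, 1))
    if n == 2:
        a = np.arange(m + 1) / m
        return np.column_stack([a, 1.0 - a])
    if n == 3:
        i, j = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
        keep = (i + j) <= m
        a, b = i[keep], j[keep]
        return np.column_stack([a, b, m - a - b]) / m
    pts = []
    for c in itertools.combinations(range(m + n - 1), n - 1):
        parts = np.diff((-1,) + c + (m + n - 1,)) - 1
        pts.append(parts)
    return np.asarray(pts, dtype=float) / m


def _block_arrays(spec: ModelSpec, data: PanelDataset, period: str):
    """(matrix, observed-column, direction) triples per variable of the block."""
    (k,) = spec.divisions
    dv = spec.division_variables(k)
    bad_dir, good_dir = [], []  # bad_dir: benchmark must be <=, good_dir: >=
    for var in dv.inputs:
        bad_dir.append(data.column(k, var, period))
    for var in dv.bad_outputs:
        bad_dir.append(data.column(k, var, period))
    for var in dv.good_outputs:
        good_dir.append(data.column(k, var, period))
    carry = [data.column(k, c.variable, period) for c in spec.carryovers_of(k)]
    return bad_dir, good_dir, carry


def _period_terms(spec, data, o, period, grid):
    """Feasibility mask and (N, D) bracket values of every grid point."""
    (k,) = spec.divisions
    dv = spec.division_variables(k)
    dims = spec.dims(k)
    bad_dir, good_dir, carry = _block_arrays(spec, data, period)
    n_bad_out = dims.r2

    npts = grid.shape[0]
    feasible = np.ones(npts, dtype=bool)
    num = np.ones(npts)
    den = np.ones(npts)

    # inputs first in bad_dir, then bad outputs (same <= direction)
    for i, col in enumerate(bad_dir):
        bench = grid @ col
        obs = col[o]
        slack = obs - bench  # s- >= 0 required
        feasible &= slack >= -_FEAS_TOL * max(obs, 1.0)
        ratio = np.clip(slack, 0.0, None) / obs
        if i < dims.m:  # input: numerator
            num -= ratio / (dims.m + dims.linkin)
        else:  # bad output: denominator
            den += ratio / (dims.r1 + n_bad_out + dims.ngood)
    for col in good_dir:
        bench = grid @ col
        obs = col[o]
        slack = bench - obs  # s+ >= 0
        feasible &= slack >= -_FEAS_TOL * max(obs, 1.0)
        den += np.clip(slack, 0.0, None) / obs / (dims.r1 + n_bad_out + dims.ngood)
    for col in carry:
        bench = grid @ col
        obs = col[o]
        slack = bench - obs  # carry-over shortfall slack >= 0
        feasible &= slack >= -_FEAS_TOL * max(obs, 1.0)
        den += np.clip(slack, 0.0, None) / obs / (dims.r1 + n_bad_out + dims.ngood)
    return feasible, num, den


def grid_overall_efficiency(
    spec: ModelSpec,
    data: PanelDataset,
    dmu: str,
    step: float = 1e-3,
) -> float:
    """Grid-enumerated overall efficiency of one DMU (K = 1, T <= 2, n <= 3)."""
    spec = validate_spec(spec)
    if not data.validated:
        data = validate_dataset(spec, data)
    if len(spec.divisions) != 1:
        raise ValueError("grid oracle handles single-division models only")
    if data.n_periods > 2:
        raise ValueError("grid oracle handles at most two periods")
    if data.n_dmu > 3:
        raise ValueError("grid oracle handles at most three DMUs")
    (k,) = spec.divisions
    o = data.dmu_ids.index(dmu)
    wt = spec.weights.resolved_period_weights(data.n_periods)
    grid = simplex_grid(data.n_dmu, step)

    masks, nums, dens = [], [], []
    for t in data.periods:
        feasible, num, den = _period_terms(spec, data, o, t, grid)
        if not feasible.any():
            raise ValueError(f"no feasible grid point in period {t!r}")
        masks.append(feasible)
        nums.append(num)
        dens.append(den)

    if data.n_periods == 1:
        f, n_, d_ = masks[0], nums[0], dens[0]
        return float(np.min(n_[f] / d_[f]))

    carries = spec.carryovers_of(k)
    if carries:
        if data.n_dmu > 2:
            raise ValueError(
                "continuity-coupled grid enumeration supports at most two DMUs"
            )
        # pairwise enumeration with the exact continuity constraint
        t1 = data.periods[0]
        best = np.inf
        carry_cols = [data.column(k, c.variable, t1) for c in carries]
        f1, f2 = masks
        idx1 = np.nonzero(f1)[0]
        idx2 = np.nonzero(f2)[0]
        flows = [grid @ col for col in carry_cols]
        scale = [max(abs(fl).max(), 1.0) for fl in flows]
        ok = np.ones((idx1.size, idx2.size), dtype=bool)
        for fl, sc in zip(flows, scale):
            diff = np.abs(fl[idx1][:, None] - fl[idx2][None, :])
            ok &= diff <= 1e-9 * sc
        if not ok.any():
            raise ValueError("no grid point pair satisfies carry-over continuity")
        total_n = wt[0] * nums[0][idx1][:, None] + wt[1] * nums[1][idx2][None, :]
        total_d = wt[0] * dens[0][idx1][:, None] + wt[1] * dens[1][idx2][None, :]
        best = np.min(total_n[ok] / total_d[ok])
        return float(best)

    # uncoupled periods: Dinkelbach iteration over the per-period grids
    n1, d1 = wt[0] * nums[0][masks[0]], wt[0] * dens[0][masks[0]]
    n2, d2 = wt[1] * nums[1][masks[1]], wt[1] * dens[1][masks[1]]
    theta = 1.0
    for _ in range(100):
        i = int(np.argmin(n1 - theta * d1))
        j = int(np.argmin(n2 - theta * d2))
        new_theta = (n1[i] + n2[j]) / (d1[i] + d2[j])
        if abs(new_theta - theta) <= 1e-13:
            theta = new_theta
            break
        theta = new_theta
    return float(theta)
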