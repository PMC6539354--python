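"""Period, division and division-period efficiency decompositions.

All three scores are read off the bracket values N_k^t and D_k^t of the
overall-optimal slack solution (single optimization per DMU):

* period efficiency      (sum_k W^k N_k^t) / (sum_k W^k D_k^t)
* division efficiency    (sum_t W^t N_k^t) / (sum_t W^t D_k^t)
* division-period score  N_k^t / D_k^t

The overall score is the weighted mediant of the period (equivalently
division) numerators and denominators, hence always bracketed by the
smallest and largest period score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .engine import SlackSolution


def period_efficiency(sol: SlackSolution, period: str) -> float:
    """Efficiency of one period, aggregated over divisions."""
    if period not in sol.period_weights:
        raise KeyError(f"unknown period {period!r}")
    wk = sol.division_weights
    num = sum(w * sol.num_parts[(k, period)] for k, w in wk.items())
    den = sum(w * sol.den_parts[(k, period)] for k, w in wk.items())
    return num / den


def division_efficiency(sol: SlackSolution, division: str) -> float:
    """Efficiency of one division, aggregated over periods."""
    if division not in sol.division_weights:
        raise KeyError(f"unknown division {division!r}")
    wt = sol.period_weights
    num = sum(w * sol.num_parts[(division, t)] for t, w in wt.items())
    den = sum(w * sol.den_parts[(division, t)] for t, w in wt.items())
    return num / den


def division_period_efficiency(sol: SlackSolution, division: str, period: str) -> float:
    """Efficiency of one (division, period) cell."""
    key = (division, period)
    if key not in sol.num_parts:
        raise KeyError(f"unknown (division, period) {key}")
    return sol.num_parts[key] / sol.den_parts[key]


@dataclass
class EfficiencyReport:
    """Overall/period/division/division-period scores for a set of DMUs.

    ``overall`` is indexed by dmu; ``period``/``division`` are DMU-by-label
    frames; ``division_period`` has a (period, division) column MultiIndex.
    """

    overall: pd.Series
    period: pd.DataFrame
    division: pd.DataFrame
    division_period: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def efficiency_report(
    solutions: list[SlackSolution], metadata: Optional[dict] = None
) -> EfficiencyReport:
    """Tabulate all four score families for a batch of solutions."""
    ok = [s for s in solutions if s.status != "failed"]
    if not ok:
        raise ValueError("no successfully solved DMUs to report")
    periods = ok[0].periods
    divisions = ok[0].divisions
    dmus = [s.dmu for s in ok]
    overall = pd.Series({s.dmu: s.theta for s in ok}, name="overall")
    period = pd.DataFrame(
        {t: [period_efficiency(s, t) for s in ok] for t in periods}, index=dmus
    )
    division = pd.DataFrame(
        {k: [division_efficiency(s, k) for s in ok] for k in divisions}, index=dmus
    )
    cols = pd.MultiIndex.from_product([periods, divisions], names=["period", "division"])
    division_period = pd.DataFrame(
        [
            [division_period_efficiency(s, k, t) for t in periods for k in divisions]
            for s in ok
        ],
        index=dmus,
        columns=cols,
    )
    meta = dict(metadata or {})
    meta.setdefault("period_weights", ok[0].period_weights)
    meta.setdefault("division_weights", ok[0].division_weights)
    failed = [s.dmu for s in solutions if s.status == "failed"]
    if failed:
        meta["failed_dmus"] = failed
    return EfficiencyReport(
        overall=overall,
        period=period,
        division=division,
        division_period=division_period,
        metadata=meta,
    )
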