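"""Model and results objects for dynamic network SBM-DEA.

`DynamicNetworkSBM` pairs a :class:`~dndea.spec.ModelSpec` with a
:class:`~dndea.panel.PanelDataset`; :meth:`DynamicNetworkSBM.fit` solves
the slacks-based program for every DMU and returns a :class:`DEAResults`
carrying overall/period/division/division-period efficiencies, optimal
slacks and per-variable factor indices, with a text ``summary()``.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from . import decomposition as dec
from . import engine, factors
from .panel import PanelDataset, read_panel_csv, validate_dataset
from .spec import ModelSpec, validate_spec

__all__ = ["DynamicNetworkSBM", "DEAResults"]


class DynamicNetworkSBM:
    """Non-oriented dynamic network slacks-based-measure model (VRS).

    Parameters
    ----------
    spec
        Model topology (divisions, roles, links, carry-overs, weights).
    data
        Panel of observed values; validated (and zero-cleaned) on entry.
    link_continuity
        Also tie the producing and receiving intensity blocks of every
        link variable together (off by default; the baseline model only
        constrains the receiving side).
    reoptimize_decompositions
        Re-optimize each period/division/division-period score with its
        own restricted objective instead of reading all decompositions
        off the overall-optimal slacks.
    """

    def __init__(
        self,
        spec: ModelSpec,
        data: PanelDataset,
        *,
        link_continuity: bool = False,
        reoptimize_decompositions: bool = False,
        solver_options: Optional[dict] = None,
    ):
        self.spec = validate_spec(spec)
        self.data = data if data.validated else validate_dataset(self.spec, data)
        self.link_continuity = link_continuity
        self.reoptimize_decompositions = reoptimize_decompositions
        self.solver_options = solver_options

    @classmethod
    def from_csv(cls, data_path, spec_path, **kwargs) -> "DynamicNetworkSBM":
        with open(spec_path) as fh:
            spec = ModelSpec.from_json(fh.read())
        return cls(spec, read_panel_csv(data_path), **kwargs)

    def fit(self, dmus: Optional[list[str]] = None) -> "DEAResults":
        """Solve every DMU (or a subset) and assemble the results."""
        if dmus is None:
            solutions = engine.solve_all(
                self.spec,
                self.data,
                link_continuity=self.link_continuity,
                solver_options=self.solver_options,
            )
        else:
            solutions = [self.fit_dmu(d) for d in sorted(dmus)]
        report = dec.efficiency_report(
            solutions,
            metadata={
                "link_continuity": self.link_continuity,
                "reoptimize_decompositions": self.reoptimize_decompositions,
            },
        )
        if self.reoptimize_decompositions:
            self._reoptimize(report)
        table = factors.tabulate_indices(solutions, self.spec)
        return DEAResults(self, solutions, report, table)

    def fit_dmu(self, dmu: str) -> engine.SlackSolution:
        return engine.solve_dmu(
            self.spec,
            self.data,
            dmu,
            link_continuity=self.link_continuity,
            solver_options=self.solver_options,
        )

    def _reoptimize(self, report: dec.EfficiencyReport) -> None:
        periods = list(report.period.columns)
        divisions = list(report.division.columns)
        for dmu in report.overall.index:
            for t in periods:
                report.period.loc[dmu, t] = engine.restricted_score(
                    self.spec, self.data, dmu, periods=[t],
                    link_continuity=self.link_continuity,
                    solver_options=self.solver_options,
                )
            for k in divisions:
                report.division.loc[dmu, k] = engine.restricted_score(
                    self.spec, self.data, dmu, divisions=[k],
                    link_continuity=self.link_continuity,
                    solver_options=self.solver_options,
                )
            for t in periods:
                for k in divisions:
                    report.division_period.loc[dmu, (t, k)] = engine.restricted_score(
                        self.spec, self.data, dmu, periods=[t], divisions=[k],
                        link_continuity=self.link_continuity,
                        solver_options=self.solver_options,
                    )


class DEAResults:
    """Fitted efficiencies, slacks and factor indices for a panel."""

    def __init__(self, model, solutions, report, factor_indices):
        self.model = model
        self.solutions = {s.dmu: s for s in solutions}
        self.report = report
        self.factor_indices = factor_indices

    # -- convenient views ---------------------------------------------------

    @property
    def overall(self) -> pd.Series:
        """Overall efficiency theta* per DMU."""
        return self.report.overall

    @property
    def period_scores(self) -> pd.DataFrame:
        return self.report.period

    @property
    def division_scores(self) -> pd.DataFrame:
        return self.report.division

    @property
    def division_period_scores(self) -> pd.DataFrame:
        return self.report.division_period

    def efficient_dmus(self, tol: float = 1e-6) -> list[str]:
        return [d for d, v in self.overall.items() if v >= 1.0 - tol]

    # -- presentation -------------------------------------------------------

    def summary(self, precision: int = 6) -> str:
        """Plain-text summary in the style of statistical model results."""
        spec = self.model.spec
        data = self.model.data
        lines = []
        title = "Dynamic Network SBM (non-oriented, VRS, undesirable outputs)"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"DMUs: {data.n_dmu}    Periods: {data.n_periods}    "
                     f"Divisions: {len(spec.divisions)}")
        lines.append(f"Division order: {', '.join(spec.divisions)}")
        wt = spec.weights.resolved_period_weights(data.n_periods)
        wk = spec.weights.resolved_division_weights(len(spec.divisions))
        lines.append(f"Period weights: {[round(float(v), 4) for v in wt]}")
        lines.append(f"Division weights: {[round(float(v), 4) for v in wk]}")
        lines.append(f"Efficient DMUs: {len(self.efficient_dmus())} of {data.n_dmu}")
        lines.append("")
        frame = pd.concat(
            [self.overall.rename("overall"), self.period_scores], axis=1
        ).round(precision)
        lines.append(frame.to_string())
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<DEAResults: {len(self.solutions)} DMUs, "
            f"mean overall {self.overall.mean():.4f}>"
        )
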