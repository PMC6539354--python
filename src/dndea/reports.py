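"""Report writers and saved-result verification.

Outputs of a fitted model, written to an output directory:

* ``overall.csv``  - DMU x period matrix of period efficiencies
* ``stages.csv``   - DMU x (period-division) division-period scores, with
  columns labelled like ``2013-I, 2013-II, ...`` (divisions numbered by
  spec order)
* ``factors.csv``  - per-variable factor indices, columns ``period variable``
* ``results.json`` - machine-readable scores, slacks and intensities

All CSVs are UTF-8 with '.' decimal separator and no thousands separators.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SlackSolution, verify_solution
from .exceptions import ReportError
from .panel import PanelDataset
from .spec import ModelSpec

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _roman(i: int) -> str:
    return _ROMAN[i] if i < len(_ROMAN) else str(i + 1)


def write_reports(results, outdir, precision: int = 6) -> dict[str, Path]:
    """Write all report files for a :class:`~dndea.model.DEAResults`.

    Refuses to write when no DMU was solved.  Returns the paths written.
    """
    if precision < 1:
        raise ReportError("precision must be at least 1 digit")
    if len(results.solutions) == 0 or results.overall.empty:
        raise ReportError("refusing to write reports for an empty result set")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = results.model.spec

    paths = {}
    overall = results.period_scores.round(precision)
    overall.index.name = "dmu"
    paths["overall"] = outdir / "overall.csv"
    overall.to_csv(paths["overall"])

    stages = results.division_period_scores.copy()
    div_label = {k: _roman(i) for i, k in enumerate(spec.divisions)}
    stages.columns = [f"{t}-{div_label[k]}" for t, k in stages.columns]
    stages.index.name = "dmu"
    paths["stages"] = outdir / "stages.csv"
    stages.round(precision).to_csv(paths["stages"])

    wide = results.factor_indices.pivot_table(
        index="dmu", columns=["variable", "period"], values="index", sort=False
    )
    wide.columns = [f"{t} {v}" for v, t in wide.columns]
    paths["factors"] = outdir / "factors.csv"
    wide.round(precision).to_csv(paths["factors"])

    payload = {
        "metadata": {
            **results.report.metadata,
            "divisions": list(spec.divisions),
            "periods": list(results.period_scores.columns),
            "precision": precision,
        },
        "overall": {d: float(v) for d, v in results.overall.items()},
        "period": _frame_dict(results.period_scores),
        "division": _frame_dict(results.division_scores),
        "division_period": {
            dmu: {
                f"{t}|{k}": float(v)
                for (t, k), v in results.division_period_scores.loc[dmu].items()
            }
            for dmu in results.division_period_scores.index
        },
        "slacks": {
            dmu: {"|".join(key): float(v) for key, v in sol.slacks.items()}
            for dmu, sol in results.solutions.items()
        },
        "lambda": {
            dmu: {
                f"{k}|{t}": [float(v) for v in vec]
                for (k, t), vec in sol.lam.items()
            }
            for dmu, sol in results.solutions.items()
        },
        "dmu_order": list(results.model.data.dmu_ids),
    }
    paths["results"] = outdir / "results.json"
    paths["results"].write_text(json.dumps(payload, indent=1))
    return paths


def _frame_dict(frame: pd.DataFrame) -> dict:
    return {str(i): {str(c): float(frame.loc[i, c]) for c in frame.columns} for i in frame.index}


def verify_saved_results(
    results_path,
    spec: ModelSpec,
    data: PanelDataset,
    tol: float = 1e-6,
) -> dict:
    """Re-check a written ``results.json`` against its inputs.

    Rebuilds each DMU's constraint system from the spec and panel,
    evaluates the recorded intensities and slacks, and recomputes the
    overall score from the recorded slack profile.  Returns a report dict
    with per-DMU max residual and score discrepancy.
    """
    payload = json.loads(Path(results_path).read_text())
    link_continuity = bool(payload["metadata"].get("link_continuity", False))
    report = {"dmus": {}, "passed": True, "tol": tol}
    from .engine import assemble_program  # local import to avoid cycle at module load

    for dmu, theta in payload["overall"].items():
        fp = assemble_program(spec, data, dmu, link_continuity=link_continuity)
        lam = {
            kt: np.asarray(payload["lambda"][dmu][f"{kt[0]}|{kt[1]}"])
            for kt in fp.lam_idx
        }
        slacks = {
            key: float(payload["slacks"][dmu]["|".join(key)]) for key in fp.slack_idx
        }
        sol = SlackSolution(
            dmu=dmu,
            theta=float(theta),
            status="recorded",
            lam=lam,
            slacks=slacks,
            observed={key: fp.slack_obs[i] for key, i in fp.slack_idx.items()},
            num_parts={},
            den_parts={},
            period_weights=fp.period_weights,
            division_weights=fp.division_weights,
            residuals={},
            link_continuity=link_continuity,
        )
        ver = verify_solution(sol, spec, data, tol=tol)
        num = sum(
            fp.weight[kt]
            * (1.0 + sum(c * slacks[_key_of(fp, i)] for i, c in fp.bracket_num[kt].items()))
            for kt in fp.weight
        )
        den = sum(
            fp.weight[kt]
            * (1.0 + sum(c * slacks[_key_of(fp, i)] for i, c in fp.bracket_den[kt].items()))
            for kt in fp.weight
        )
        gap = abs(num / den - float(theta))
        ok = ver.passed and gap <= tol
        report["dmus"][dmu] = {
            "max_residual": ver.max_residual,
            "theta_gap": gap,
            "passed": ok,
        }
        report["passed"] &= ok
    return report


def _key_of(fp, idx: int):
    if not hasattr(fp, "_rev_slack"):
        fp._rev_slack = {i: key for key, i in fp.slack_idx.items()}
    return fp._rev_slack[idx]
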