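"""Panel data container and long-CSV I/O.

The observed data are a long table with one row per
(dmu, period, division, variable): inputs x, good outputs y+, bad outputs
y-, link values z_in (stored under the division that produces them) and
good carry-overs z_good (the stock carried out of each period t).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import (
    CompletenessError,
    DomainError,
    PanelParseError,
    SchemaError,
)
from .spec import ROLES, ModelSpec, validate_spec

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["dmu", "period", "division", "variable", "role", "value"]

#: zeros are replaced by this fraction of the variable's smallest positive value
ZERO_EPS = 1e-6


class PanelDataset:
    """Observed panel values over (dmu, period, division, variable).

    Ordering of DMUs and periods is by first appearance in the long table
    unless overridden; period order matters because carry-over continuity
    chains consecutive periods.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        dmu_ids: Optional[list[str]] = None,
        periods: Optional[list[str]] = None,
    ):
        missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
        if missing:
            raise PanelParseError(f"panel frame is missing columns {missing}")
        frame = frame.loc[:, PANEL_COLUMNS].copy()
        frame["value"] = frame["value"].astype(float)
        for col in ("dmu", "period", "division", "variable", "role"):
            frame[col] = frame[col].astype(str)
        self._frame = frame.reset_index(drop=True)
        self.dmu_ids = list(dmu_ids) if dmu_ids is not None else list(
            dict.fromkeys(self._frame["dmu"])
        )
        self.periods = list(periods) if periods is not None else list(
            dict.fromkeys(self._frame["period"])
        )
        self.validated = False
        self._dense: Optional[dict[tuple[str, str], np.ndarray]] = None

    # -- basic properties ---------------------------------------------------

    @property
    def n_dmu(self) -> int:
        return len(self.dmu_ids)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def to_long(self) -> pd.DataFrame:
        return self._frame.copy()

    # -- dense access (built by validate_dataset) ---------------------------

    def _build_dense(self) -> None:
        dense: dict[tuple[str, str], np.ndarray] = {}
        dmu_pos = {d: i for i, d in enumerate(self.dmu_ids)}
        per_pos = {p: i for i, p in enumerate(self.periods)}
        for (division, variable), grp in self._frame.groupby(
            ["division", "variable"], sort=False
        ):
            arr = np.full((self.n_periods, self.n_dmu), np.nan)
            arr[
                grp["period"].map(per_pos).to_numpy(),
                grp["dmu"].map(dmu_pos).to_numpy(),
            ] = grp["value"].to_numpy()
            dense[(division, variable)] = arr
        self._dense = dense

    def column(self, division: str, variable: str, period: str) -> np.ndarray:
        """Values of one variable for all DMUs (dataset order) at ``period``."""
        if self._dense is None:
            self._build_dense()
        try:
            arr = self._dense[(division, variable)]
        except KeyError:
            raise KeyError(f"no variable {variable!r} in division {division!r}") from None
        return arr[self.periods.index(period)]

    def value(self, dmu: str, period: str, division: str, variable: str) -> float:
        return float(self.column(division, variable, period)[self.dmu_ids.index(dmu)])

    # -- functional updates (used by property tests) ------------------------

    def scaled(self, division: str, variable: str, factor: float) -> "PanelDataset":
        """New dataset with one variable's column multiplied by ``factor``."""
        frame = self._frame.copy()
        mask = (frame["division"] == division) & (frame["variable"] == variable)
        if not mask.any():
            raise KeyError(f"no variable {variable!r} in division {division!r}")
        frame.loc[mask, "value"] *= factor
        return PanelDataset(frame, self.dmu_ids, self.periods)

    def replaced(
        self, dmu: str, period: str, division: str, variable: str, value: float
    ) -> "PanelDataset":
        """New dataset with a single cell replaced."""
        frame = self._frame.copy()
        mask = (
            (frame["dmu"] == dmu)
            & (frame["period"] == period)
            & (frame["division"] == division)
            & (frame["variable"] == variable)
        )
        if not mask.any():
            raise KeyError(f"no cell ({dmu}, {period}, {division}, {variable})")
        frame.loc[mask, "value"] = value
        return PanelDataset(frame, self.dmu_ids, self.periods)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "PanelDataset":
        return cls(pd.DataFrame.from_records(list(records)))


def validate_dataset(
    spec: ModelSpec, data: PanelDataset, zero_eps: float = ZERO_EPS
) -> PanelDataset:
    """Check a panel against a spec and return a cleaned copy.

    Enforces completeness (every declared (division, variable) present for
    every (dmu, period), no duplicates), role agreement with the spec, and
    positivity.  Zero cells are replaced by ``zero_eps`` times the smallest
    positive value of that variable across the panel (the SBM objective
    divides slacks by observed values, so exact zeros are inadmissible);
    each replacement emits a warning.
    """
    spec = validate_spec(spec)
    frame = data.to_long()

    if spec.periods is not None:
        extra = set(frame["period"]) - set(spec.periods)
        if extra:
            raise SchemaError(f"panel has periods not declared in the spec: {sorted(extra)}")
        missing_periods = [p for p in spec.periods if p not in set(frame["period"])]
        if missing_periods:
            raise CompletenessError(f"panel is missing declared periods {missing_periods}")
        periods = list(spec.periods)
    else:
        periods = list(dict.fromkeys(frame["period"]))
    dmu_ids = list(dict.fromkeys(frame["dmu"]))
    if not dmu_ids:
        raise CompletenessError("panel contains no DMUs")

    expected_role = {(d, v): r for d, v, r in spec.storage_cells()}
    for row in frame.itertuples(index=False):
        key = (row.division, row.variable)
        if key not in expected_role:
            raise SchemaError(
                f"variable {row.variable!r} in division {row.division!r} is not declared"
            )
        if row.role not in ROLES:
            raise SchemaError(f"unknown role token {row.role!r}")
        if row.role != expected_role[key]:
            raise SchemaError(
                f"variable {row.variable!r} in division {row.division!r} has role "
                f"{row.role!r}, spec declares {expected_role[key]!r}"
            )

    dup = frame.duplicated(subset=["dmu", "period", "division", "variable"])
    if dup.any():
        first = frame[dup].iloc[0]
        raise CompletenessError(
            f"duplicate cell ({first['dmu']}, {first['period']}, "
            f"{first['division']}, {first['variable']})"
        )

    have = set(zip(frame["dmu"], frame["period"], frame["division"], frame["variable"]))
    for dmu in dmu_ids:
        for period in periods:
            for (division, variable), _role in expected_role.items():
                if (dmu, period, division, variable) not in have:
                    raise CompletenessError(
                        f"missing cell ({dmu}, {period}, {division}, {variable})"
                    )

    if (frame["value"] < 0).any():
        bad = frame[frame["value"] < 0].iloc[0]
        raise DomainError(
            f"negative value {bad['value']} at ({bad['dmu']}, {bad['period']}, "
            f"{bad['division']}, {bad['variable']})"
        )

    zero_mask = frame["value"] == 0
    if zero_mask.any():
        frame = frame.copy()
        for (division, variable), grp in frame[zero_mask].groupby(
            ["division", "variable"], sort=False
        ):
            col = (frame["division"] == division) & (frame["variable"] == variable)
            positives = frame.loc[col & (frame["value"] > 0), "value"]
            if positives.empty:
                raise DomainError(
                    f"variable {variable!r} in division {division!r} is identically zero"
                )
            repl = zero_eps * positives.min()
            frame.loc[col & (frame["value"] == 0), "value"] = repl
            warnings.warn(
                f"replaced {len(grp)} zero value(s) of {variable!r} in division "
                f"{division!r} by {repl:.3e}",
                stacklevel=2,
            )
            logger.warning(
                "zero replacement: %s/%s -> %.3e (%d cells)", division, variable, repl, len(grp)
            )

    cleaned = PanelDataset(frame, dmu_ids, periods)
    cleaned.validated = True
    cleaned._build_dense()
    return cleaned


# -- CSV I/O ----------------------------------------------------------------


def read_panel_csv(path) -> PanelDataset:
    """Read a long-format panel CSV.

    The header must be exactly ``dmu,period,division,variable,role,value``.
    Malformed values and duplicate cells are reported with their line
    number (1-based, counting the header as line 1).
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise PanelParseError(f"cannot parse {path}: {exc}") from exc
    if list(raw.columns) != PANEL_COLUMNS:
        raise PanelParseError(
            f"{path}: header must be {','.join(PANEL_COLUMNS)}, got {','.join(raw.columns)}"
        )
    values = pd.to_numeric(raw["value"], errors="coerce")
    if values.isna().any():
        line = int(values.index[values.isna()][0]) + 2
        raise PanelParseError(f"{path}: malformed numeric value on line {line}")
    bad_role = ~raw["role"].isin(ROLES)
    if bad_role.any():
        line = int(raw.index[bad_role][0]) + 2
        raise SchemaError(
            f"{path}: unknown role token {raw.loc[line - 2, 'role']!r} on line {line}"
        )
    dup = raw.duplicated(subset=["dmu", "period", "division", "variable"])
    if dup.any():
        line = int(raw.index[dup][0]) + 2
        raise PanelParseError(f"{path}: duplicate cell on line {line}")
    frame = raw.copy()
    frame["value"] = values
    return PanelDataset(frame)


def write_panel_csv(data: PanelDataset, path) -> None:
    data.to_long().to_csv(path, index=False)
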