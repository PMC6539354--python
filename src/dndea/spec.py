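"""Declarative model topology for dynamic network SBM-DEA.

A :class:`ModelSpec` describes the production technology being evaluated:
the divisions (network stages) of each decision-making unit, the role of
every variable inside a division (input, good output, bad output), the
inter-division link variables consumed "as inputs" by their target stage,
and the good carry-over stocks that connect a division's period *t* to
period *t+1*.  Returns to scale are variable (each intensity vector sums
to one); no constant-returns switch is exposed.

Specs are plain pydantic models and round-trip losslessly through JSON.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .exceptions import RoleConflictError, TopologyError, WeightError

ROLE_INPUT = "input"
ROLE_GOOD = "good_output"
ROLE_BAD = "bad_output"
ROLE_LINK = "link"
ROLE_CARRY = "carryover"

#: role tokens accepted in panel files
ROLES = frozenset({ROLE_INPUT, ROLE_GOOD, ROLE_BAD, ROLE_LINK, ROLE_CARRY})


class DivisionVariables(BaseModel):
    """Named variables of one division, grouped by role."""

    model_config = ConfigDict(extra="forbid")

    inputs: list[str] = Field(default_factory=list)
    good_outputs: list[str] = Field(default_factory=list)
    bad_outputs: list[str] = Field(default_factory=list)


class Link(BaseModel):
    """A variable produced by ``source`` and consumed as input by ``target``."""

    model_config = ConfigDict(extra="forbid")

    source: str
    target: str
    variable: str


class Carryover(BaseModel):
    """A good carry-over stock of ``division`` linking period t to t+1."""

    model_config = ConfigDict(extra="forbid")

    division: str
    variable: str


class WeightScheme(BaseModel):
    """Period weights W^t and division weights W^k.

    ``None`` means uniform.  Explicit weights must be strictly positive and
    are normalized to sum to one during validation; any common rescaling
    cancels in the efficiency ratio anyway.
    """

    model_config = ConfigDict(extra="forbid")

    period_weights: Optional[list[float]] = None
    division_weights: Optional[list[float]] = None

    def resolved_period_weights(self, n_periods: int) -> np.ndarray:
        return _resolve_weights(self.period_weights, n_periods, "period")

    def resolved_division_weights(self, n_divisions: int) -> np.ndarray:
        return _resolve_weights(self.division_weights, n_divisions, "division")


def _resolve_weights(raw: Optional[list[float]], n: int, kind: str) -> np.ndarray:
    if raw is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(raw, dtype=float)
    if w.size != n:
        raise WeightError(f"expected {n} {kind} weights, got {w.size}")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise WeightError(f"{kind} weights must be strictly positive and finite: {raw}")
    return w / w.sum()


@dataclass(frozen=True)
class DivisionDims:
    """Derived per-division dimensions.

    m: number of inputs; r1/r2: numbers of good/bad outputs; linkin: number
    of incoming links; ngood: number of good carry-overs.
    """

    m: int
    r1: int
    r2: int
    linkin: int
    ngood: int


class ModelSpec(BaseModel):
    """Topology of a dynamic network SBM model.

    Parameters
    ----------
    divisions
        Ordered division identifiers (k = 1..K).
    variables
        Per-division variable names by role.  Divisions absent from the
        mapping have no own inputs/outputs (they may still receive links).
    links
        Inter-division link variables; each is produced by its source
        division and enters the target division's input side.
    carryovers
        Good carry-over variables, one entry per (division, variable).
    weights
        Period/division weight scheme; uniform when omitted.
    periods
        Optional explicit period ordering.  When omitted the ordering is
        taken from the panel data (first appearance), never lexical.
    """

    model_config = ConfigDict(extra="forbid")

    divisions: list[str]
    variables: dict[str, DivisionVariables] = Field(default_factory=dict)
    links: list[Link] = Field(default_factory=list)
    carryovers: list[Carryover] = Field(default_factory=list)
    weights: WeightScheme = Field(default_factory=WeightScheme)
    periods: Optional[list[str]] = None
    returns_to_scale: Literal["vrs"] = "vrs"

    # -- topology accessors -------------------------------------------------

    def division_variables(self, division: str) -> DivisionVariables:
        return self.variables.get(division, DivisionVariables())

    def links_into(self, division: str) -> list[Link]:
        return [l for l in self.links if l.target == division]

    def links_from(self, division: str) -> list[Link]:
        return [l for l in self.links if l.source == division]

    def carryovers_of(self, division: str) -> list[Carryover]:
        return [c for c in self.carryovers if c.division == division]

    def dims(self, division: str) -> DivisionDims:
        dv = self.division_variables(division)
        return DivisionDims(
            m=len(dv.inputs),
            r1=len(dv.good_outputs),
            r2=len(dv.bad_outputs),
            linkin=len(self.links_into(division)),
            ngood=len(self.carryovers_of(division)),
        )

    def role_map(self, division: str) -> dict[str, str]:
        """Role of every variable *stored* under ``division``.

        Link variables are stored under their source division (where they
        are produced), carry-overs under their own division.
        """
        dv = self.division_variables(division)
        roles: dict[str, str] = {}
        for name in dv.inputs:
            roles[name] = ROLE_INPUT
        for name in dv.good_outputs:
            roles[name] = ROLE_GOOD
        for name in dv.bad_outputs:
            roles[name] = ROLE_BAD
        for link in self.links_from(division):
            roles[link.variable] = ROLE_LINK
        for carry in self.carryovers_of(division):
            roles[carry.variable] = ROLE_CARRY
        return roles

    def storage_cells(self) -> list[tuple[str, str, str]]:
        """All (division, variable, role) cells the panel must provide."""
        cells = []
        for division in self.divisions:
            for name, role in self.role_map(division).items():
                cells.append((division, name, role))
        return cells

    # -- serialization ------------------------------------------------------

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls.model_validate_json(text)


def validate_spec(spec: ModelSpec) -> ModelSpec:
    """Validate a model topology and normalize its weights.

    Checks division uniqueness, link/carry-over references, per-division
    role uniqueness and weight positivity; returns a spec with explicit
    weights rescaled to sum to one.  Idempotent.

    Raises
    ------
    TopologyError, RoleConflictError, WeightError
    """
    if len(spec.divisions) < 1:
        raise TopologyError("a model needs at least one division")
    if len(set(spec.divisions)) != len(spec.divisions):
        raise TopologyError(f"division identifiers not unique: {spec.divisions}")
    declared = set(spec.divisions)
    for name in spec.variables:
        if name not in declared:
            raise TopologyError(f"variables declared for unknown division {name!r}")
    for link in spec.links:
        if link.source not in declared:
            raise TopologyError(f"link source {link.source!r} is not a declared division")
        if link.target not in declared:
            raise TopologyError(f"link target {link.target!r} is not a declared division")
        if link.source == link.target:
            raise TopologyError(
                f"link {link.variable!r} connects division {link.source!r} to itself"
            )
    seen_links = set()
    for link in spec.links:
        key = (link.source, link.variable)
        if key in seen_links:
            raise TopologyError(f"duplicate link variable {link.variable!r} from {link.source!r}")
        seen_links.add(key)
    for carry in spec.carryovers:
        if carry.division not in declared:
            raise TopologyError(
                f"carry-over {carry.variable!r} references unknown division {carry.division!r}"
            )
    # per-division role uniqueness (links attach to their source division)
    for division in spec.divisions:
        dv = spec.division_variables(division)
        names = (
            list(dv.inputs)
            + list(dv.good_outputs)
            + list(dv.bad_outputs)
            + [l.variable for l in spec.links_from(division)]
            + [c.variable for c in spec.carryovers_of(division)]
        )
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RoleConflictError(
                f"variable(s) {sorted(dupes)} appear in more than one role in division {division!r}"
            )
    if spec.periods is not None and len(set(spec.periods)) != len(spec.periods):
        raise TopologyError("explicit period labels must be unique")

    weights = WeightScheme(
        period_weights=_normalized_or_none(spec.weights.period_weights, "period"),
        division_weights=_normalized_or_none(spec.weights.division_weights, "division"),
    )
    if weights.division_weights is not None and len(weights.division_weights) != len(
        spec.divisions
    ):
        raise WeightError(
            f"{len(spec.weights.division_weights)} division weights for "
            f"{len(spec.divisions)} divisions"
        )
    return spec.model_copy(update={"weights": weights})


def _normalized_or_none(raw: Optional[list[float]], kind: str) -> Optional[list[float]]:
    if raw is None:
        return None
    w = _resolve_weights(raw, len(raw), kind)
    return [float(v) for v in w]
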