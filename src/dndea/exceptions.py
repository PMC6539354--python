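"""Exception hierarchy for dndea.

Everything raised deliberately by this package derives from :class:`DEAError`,
so callers can catch one base class at CLI or notebook level.
"""


class DEAError(Exception):
    """Base class for all dndea errors."""


class TopologyError(DEAError):
    """Model topology is inconsistent (unknown division, self-link, ...)."""


class RoleConflictError(DEAError):
    """A variable name is declared under more than one role within a division."""


class WeightError(DEAError):
    """A period or division weight is nonpositive or has the wrong length."""


class CompletenessError(DEAError):
    """The panel is missing (or duplicates) a required (dmu, period, variable) cell."""


class DomainError(DEAError):
    """A panel value is outside the admissible domain (negative, or all-zero column)."""


class PanelParseError(DEAError):
    """A panel CSV file is malformed (bad header, bad value, duplicate row)."""


class SchemaError(DEAError):
    """A panel row does not match the declared model spec (unknown role/variable)."""


class SolverError(DEAError):
    """The LP solver failed or returned an unusable status."""


class LinearizationError(DEAError):
    """The Charnes-Cooper normalization row cannot be formed or satisfied."""


class InconsistencyError(DEAError):
    """An optimal slack is inconsistent with its observed value (solver artifact)."""


class GenerationError(DEAError):
    """Synthetic-data parameters are infeasible (e.g. too many planted units)."""


class ReportError(DEAError):
    """Report writing was refused (e.g. empty result set)."""
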