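"""Exception hierarchy for fermkin.

All package errors derive from :class:`FermkinError` so callers can catch
one base class; most also derive from the matching builtin (ValueError or
RuntimeError) so idiomatic handling keeps working.
"""


class FermkinError(Exception):
    """Base class for all fermkin errors."""


class InvalidConstantsError(FermkinError, ValueError):
    """Incubation constants violate their invariants (e.g. V or T <= 0)."""


class DomainError(FermkinError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InconsistentTraceError(FermkinError, ValueError):
    """Cumulative gas reconstruction decreases without a vent event."""


class DegenerateInputError(FermkinError, ValueError):
    """Input carries no usable signal (e.g. an all-zero gas curve)."""


class DesignError(FermkinError, ValueError):
    """An experimental design cannot be constructed as requested."""


class MissingNutrientError(FermkinError, KeyError):
    """A nutrient is absent from a composition table."""


class NoDataError(FermkinError, ValueError):
    """An aggregation was requested over an empty record set."""


class SingularDesignError(FermkinError, ValueError):
    """A regression design matrix is rank deficient."""


class ScenarioError(FermkinError, ValueError):
    """A synthetic-data scenario is internally infeasible."""


class ValidationError(FermkinError, ValueError):
    """An input file failed schema validation."""
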