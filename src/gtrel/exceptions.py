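"""Exception hierarchy for gtrel.

All gtrel errors derive from :class:`GTError` so callers can catch the
package's failures with a single except clause while still distinguishing
schema problems from statistical ones.
"""


class GTError(Exception):
    """Base class for all gtrel errors."""


class SchemaError(GTError):
    """A required column is missing or a column cannot be parsed."""


class EmptyDataError(GTError):
    """No usable observations remain after ingest filtering."""


class DesignError(GTError):
    """The design specification is internally inconsistent."""


class IdentifiabilityError(DesignError):
    """A modeled facet has a single observed condition (hidden facet)."""


class BalanceError(GTError):
    """An exact ANOVA solution was requested for an unbalanced table."""


class FamilyError(GTError):
    """Scores are incompatible with the requested distributional family."""


class ConvergenceError(GTError):
    """MCMC did not satisfy the convergence rule (split R-hat < 1.01)."""


class IncompleteComponentsError(GTError):
    """A variance component required by the design is missing."""


class UndefinedCoefficientError(GTError):
    """A reliability coefficient has a zero denominator (all variance 0)."""
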