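"""Exception hierarchy shared across the package."""


class KnockscanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(KnockscanError):
    """A model or medium file could not be parsed under its declared format."""


class ConfigurationError(KnockscanError):
    """A run configuration references ids or values that do not exist."""


class InfeasibleModelError(KnockscanError):
    """The base model admits no feasible flux distribution."""


class SolverStateError(KnockscanError):
    """The LP solver returned a numerically suspect status (not plain infeasibility)."""


class BudgetExceededError(KnockscanError):
    """A combinatorial budget (subset count, retry limit) was exceeded."""
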