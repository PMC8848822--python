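"""Exception hierarchy for extnca."""


class ExtNCAError(Exception):
    """Base class for all extnca errors."""


class DegenerateScopeError(ExtNCAError):
    """Raised when x or y has zero range, so the scope rectangle has no area
    and effect sizes are undefined."""


class InsufficientDataError(ExtNCAError):
    """Raised when fewer than the minimum number of complete observation
    pairs are available."""


class MissingColumnError(ExtNCAError, KeyError):
    """Raised when a requested column is absent from an input table."""


class ParameterError(ExtNCAError, ValueError):
    """Raised for infeasible generator or analysis parameters."""
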