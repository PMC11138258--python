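"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors are click's (exit 2),
ValidationError and ConfigurationError map to 3, data-quality failures
(InsufficientDataError, EmptyResultError) map to 4.
"""


class EegretestError(Exception):
    """Base class for all package errors."""


class ValidationError(EegretestError):
    """An input violates a documented invariant or contract."""


class FormatError(ValidationError):
    """A file does not conform to its declared format (e.g. malformed EDF header)."""


class UnsupportedInputError(ValidationError):
    """The input is well-formed but outside the supported subset (e.g. mixed sampling rates)."""


class ConfigurationError(EegretestError):
    """A configuration value is inconsistent or infeasible."""


class InfeasibleDesignError(ConfigurationError):
    """A study-design request has no solution in the admissible range."""


class InsufficientDataError(EegretestError):
    """Too few complete observations to run the requested analysis."""


class EmptyResultError(InsufficientDataError):
    """An operation removed every observation (e.g. all epochs rejected)."""
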