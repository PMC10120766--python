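"""Exception hierarchy.

All package errors derive from :class:`TrajmixError` so callers can catch one
type; the subclasses distinguish user-configuration mistakes from data
problems and numerical failures, which the CLI maps to distinct exit codes.
"""


class TrajmixError(Exception):
    """Base class for all trajmix errors."""

    category = "error"


class ConfigurationError(TrajmixError):
    """A requested column, option, or model setting is invalid."""

    category = "configuration"


class DataError(TrajmixError):
    """The data are unusable for the requested operation."""

    category = "data"


class DomainError(TrajmixError):
    """A structural-model argument is outside its mathematical domain."""

    category = "domain"


class InitializationError(TrajmixError):
    """The fit could not start (e.g. non-finite likelihood at the initials)."""

    category = "initialization"
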