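"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3.
"""


class HomecageError(Exception):
    """Base class for all package errors."""


class ConfigError(HomecageError):
    """Invalid configuration, schedule request, or parameter value."""


class DataError(HomecageError):
    """Problem with event data content (missing sessions, unknown animals...)."""


class FormatError(DataError):
    """Malformed input file (missing columns, unparsable values)."""


class ValidationError(DataError):
    """Event data violates a model invariant that cannot be repaired."""
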