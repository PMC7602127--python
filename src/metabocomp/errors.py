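"""Exception hierarchy shared across the package.

Two failure families matter to callers (and to the CLI's exit codes):
usage/validation problems (the caller asked for something inconsistent) and
data problems (the inputs themselves are unreadable or malformed).
"""


class MetabocompError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(MetabocompError):
    """Inconsistent parameters or inputs violating a documented contract."""

    exit_code = 1


class UsageError(MetabocompError):
    """Bad invocation: unknown option value, missing upstream artifact."""

    exit_code = 1


class DataError(MetabocompError):
    """Unreadable, garbled or empty input data."""

    exit_code = 2


class ParseError(DataError):
    """A file or string could not be parsed; message names the location."""


class EmptyRunError(DataError):
    """A run contains no scans at the requested MS levels."""
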