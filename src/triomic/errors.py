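"""Exception hierarchy shared across the pipeline.

Each family maps to a distinct CLI exit code so shell callers can tell
malformed data apart from missing files or a bad configuration.
"""


class TriomicError(Exception):
    """Base class for all package-raised errors."""

    exit_code = 1


class FormatError(TriomicError):
    """A file does not match the documented tabular layout (e.g. a missing column)."""

    exit_code = 2


class ValidationError(TriomicError):
    """Parsed content violates a domain invariant (e.g. contradictory directions)."""

    exit_code = 2


class InputError(TriomicError):
    """An input path cannot be read."""

    exit_code = 3


class ConfigError(TriomicError):
    """Pipeline configuration is inconsistent or out of range."""

    exit_code = 4
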