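"""Exception hierarchy.

``UserError`` subclasses map to CLI exit code 1 (bad input, bad config);
anything else that escapes is an internal error (exit code 2).
"""


class PbcnetError(Exception):
    """Base class for all package errors."""


class UserError(PbcnetError):
    """An error attributable to user input (files, config, parameters)."""


class ConfigurationError(UserError):
    """Invalid configuration value; the message names the offending field."""


class ValidationError(UserError):
    """Invalid argument passed to a library function."""


class ParseError(UserError):
    """Malformed input file."""


class InputError(UserError):
    """Missing or unusable input data."""


class ConvergenceError(PbcnetError):
    """Iterative solver failed to reach tolerance; carries the last residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
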