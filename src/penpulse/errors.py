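"""Exception and warning hierarchy.

``ParameterError`` marks a misuse of the API or configuration (CLI exit
code 2); ``DataError`` marks inputs that are structurally valid requests
but unusable data (CLI exit code 3).
"""


class PenPulseError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PenPulseError, ValueError):
    """Invalid parameter, configuration value, or API misuse."""


class DataError(PenPulseError, ValueError):
    """Input data violate a structural or physiological precondition."""


class FormatError(DataError):
    """A file does not conform to the expected layout."""


class PenPulseWarning(UserWarning):
    """Diagnostic condition that does not abort processing."""
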