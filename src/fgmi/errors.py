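"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, numeric failures exit 4.
"""


class FgmiError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FgmiError, ValueError):
    """Invalid configuration (bad K, non-positive alpha, inconsistent grids...)."""


class DataFormatError(FgmiError, ValueError):
    """Malformed input data (ragged rows, non-numeric cells, bad labels...)."""


class ModelIOError(FgmiError, ValueError):
    """A serialized model artifact could not be read or is inconsistent."""


class NumericError(FgmiError, ArithmeticError):
    """A numeric routine failed (non-finite values, solver breakdown)."""
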