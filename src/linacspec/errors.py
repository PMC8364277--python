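"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2, ``NumericalError`` to 3.
"""


class LinacspecError(Exception):
    """Base class for all package errors."""


class ValidationError(LinacspecError, ValueError):
    """Invalid input: bad file contents, inconsistent grids, out-of-range
    parameters."""


class NumericalError(LinacspecError, ArithmeticError):
    """A computation could not proceed (e.g. a response matrix that cannot
    explain strictly positive measured counts)."""
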