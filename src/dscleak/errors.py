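"""Exception hierarchy for the pipeline.

Input/contract problems raise :class:`ValidationError`; numerical failures
(degenerate curves, impossible normalization) raise :class:`NumericalError`.
The CLI maps these to exit codes 2 and 3 respectively.
"""


class DSCLeakError(Exception):
    """Base class for all package errors."""


class ValidationError(DSCLeakError, ValueError):
    """Invalid input data or configuration."""


class NumericalError(DSCLeakError, RuntimeError):
    """A computation could not be carried out on the given data."""
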