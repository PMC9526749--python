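"""Exception hierarchy.

Validation errors signal malformed data; parameter errors signal bad
configuration; capacity errors signal an unsatisfiable simulation layout.
"""


class CirloopError(Exception):
    """Base class for all package errors."""


class ValidationError(CirloopError):
    """Malformed input data (bad coordinates, alphabets, mismatched labels)."""


class ParameterError(CirloopError):
    """Invalid parameter value (negative gap, zero library size, ...)."""


class CapacityError(CirloopError):
    """Simulation layout cannot be placed in the requested genome."""


class UndefinedCorrelationError(CirloopError):
    """Correlation undefined: too few pairs or a zero-variance vector."""


class DivideByZeroFoldError(CirloopError):
    """Fold change denominator is zero; add a pseudocount via configuration."""
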