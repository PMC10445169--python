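"""Exception types shared across the package."""


class PasmatchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PasmatchError, ValueError):
    """A file does not conform to its expected text format."""


class ValidationError(PasmatchError, ValueError):
    """Data violate a domain invariant (negative expression, duplicate ids, ...)."""


class UndefinedStatisticError(PasmatchError, ValueError):
    """A statistic is mathematically undefined for the given input
    (e.g. Pearson correlation of a constant vector)."""


class ConvergenceError(PasmatchError, RuntimeError):
    """An iterative fit failed to converge; carries residual diagnostics."""
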