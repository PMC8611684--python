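"""Exception hierarchy shared across the package."""


class UmaError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(UmaError, ValueError):
    """Model parameters or doses are non-finite / structurally invalid."""


class DomainError(UmaError, ValueError):
    """Inputs lie outside the mathematical domain of an operation."""


class DataError(UmaError, ValueError):
    """Assay data are malformed or insufficient."""


class ConvergenceError(UmaError, RuntimeError):
    """A numerical search or integrator failed to converge."""
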