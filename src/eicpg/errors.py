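"""Package-wide exception types."""


class EICPGError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EICPGError, ValueError):
    """A parameter is outside its admissible range."""


class InfeasibleImbalanceError(EICPGError, ValueError):
    """The requested imbalance cannot be realized under the given constraint."""


class NumericalDivergenceError(EICPGError, RuntimeError):
    """Network activations left the finite range during integration."""


class SolverFailureError(EICPGError, RuntimeError):
    """Self-consistent mean-field solver did not converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class TrainingDivergenceError(EICPGError, RuntimeError):
    """Readout training produced non-finite weights."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
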