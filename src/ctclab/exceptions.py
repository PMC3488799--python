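"""Package-wide exception types."""


class CtclabError(Exception):
    """Base class for all ctclab errors."""


class BoundsError(CtclabError, ValueError):
    """A genotype or parameter violated its declared bounds."""


class SimulationBlowupError(CtclabError, ArithmeticError):
    """Numerical integration produced a non-finite or runaway state.

    Attributes
    ----------
    time_ms : float
        Simulation time at which the failure was detected.
    """

    def __init__(self, message: str, time_ms: float = float("nan")):
        super().__init__(message)
        self.time_ms = time_ms


class UndefinedAPDError(CtclabError, ValueError):
    """The requested repolarization crossing does not occur within the beat."""


class AlignmentError(CtclabError, ValueError):
    """A trace never crosses the upstroke-alignment threshold."""


class TraceFormatError(CtclabError, ValueError):
    """A voltage-trace file is malformed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class CalibrationError(CtclabError, RuntimeError):
    """Template calibration could not bracket the requested APD."""
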