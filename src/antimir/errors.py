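"""Exception taxonomy shared across the package."""


class AntimirError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AntimirError, ValueError):
    """Invalid parameter, missing scaling rule, or malformed input spec."""


class SimulationError(AntimirError, RuntimeError):
    """ODE integration failed; carries the last successful time if known."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class NumericalIntegrityError(AntimirError, RuntimeError):
    """State excursion beyond the tolerated negativity bound."""


class UndefinedMetricError(AntimirError, ValueError):
    """A response metric is undefined for the given inputs (e.g. TGI with a
    non-growing control, %ID of a zero dose, correlation of a constant vector)."""
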