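"""Exception hierarchy shared across the package."""


class FlavopathError(Exception):
    """Base class for all package errors."""


class TopologyError(FlavopathError, ValueError):
    """Invalid pathway topology (cycle, dangling species, duplicate edge, ...)."""


class InputError(FlavopathError, ValueError):
    """Malformed user input (tables, descriptors, configs)."""


class DomainError(FlavopathError, ValueError):
    """Evaluation requested outside a curve's or profile's time domain."""


class IntegrationError(FlavopathError, RuntimeError):
    """ODE integration failed; carries the last valid time reached."""

    def __init__(self, message: str, last_valid_time: float | None = None):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class OptimizationError(FlavopathError, RuntimeError):
    """Optimizer could not produce a finite-objective solution."""
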