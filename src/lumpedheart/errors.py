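"""Exception hierarchy shared across the package."""


class LumpedHeartError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LumpedHeartError, ValueError):
    """A record is missing a mandatory field or has a malformed one."""


class ValidationError(LumpedHeartError, ValueError):
    """A record or parameter set violates a physiological invariant."""


class DomainError(LumpedHeartError, ValueError):
    """A scalar input lies outside the mathematical domain of an operation."""


class StateError(LumpedHeartError, RuntimeError):
    """An operation was invoked in the wrong order or on uninitialised state."""


class SolverError(LumpedHeartError, RuntimeError):
    """The ODE integration produced non-finite state."""


class CalibrationError(LumpedHeartError, RuntimeError):
    """A calibration (unloaded volume, Young's modulus, flow split) failed."""


class ConfigurationError(LumpedHeartError, RuntimeError):
    """A tuning step could not bracket a solution within its search range."""
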