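"""Exception hierarchy for the simulation pipeline."""


class RvsimError(Exception):
    """Base class for all package errors."""


class ParameterError(RvsimError, ValueError):
    """A parameter violates its physical or structural constraints."""


class GeometryError(RvsimError):
    """The three-wall junction solve failed to reach force balance."""


class IntegrationError(RvsimError):
    """The beat integrator failed (step underflow or geometry failure)."""


class ConvergenceError(RvsimError):
    """Periodic convergence was not reached within the beat budget."""


class CalibrationError(RvsimError):
    """A contractility or fibrosis calibration target is unattainable."""


class HomeostasisError(RvsimError):
    """Systolic arterial pressure could not be brought into range."""


class ScenarioError(RvsimError, KeyError):
    """Unknown scenario name or invalid scenario definition."""


class MetricsError(RvsimError):
    """A trajectory does not support the requested hemodynamic metric."""


class ConfigError(RvsimError):
    """Malformed configuration file or override."""
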