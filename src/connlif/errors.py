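"""Exception types shared across the package."""


class ConnlifError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ConnlifError):
    """An input table or config is missing a required column/field."""


class ConfigurationError(ConnlifError):
    """A simulation or experiment was configured inconsistently."""


class SimulationError(ConnlifError):
    """The integrator reached an invalid (non-finite) state."""


class CalibrationError(ConnlifError):
    """An input-rate calibration target could not be reached on the grid."""
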