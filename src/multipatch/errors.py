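"""Exception hierarchy for the multipatch simulator."""


class MultipatchError(Exception):
    """Base class for all package errors."""


class InvalidCircuitError(MultipatchError):
    """Electrode circuit parameters are physically inconsistent."""


class MeasurementError(MultipatchError):
    """The seal test produced no usable current (amplifier/valve fault)."""


class InsufficientHistoryError(MultipatchError):
    """Fewer resistance estimates than the averaging window requires."""


class ProtocolError(MultipatchError):
    """A rig or controller action attempted out of its legal phase."""


class CalibrationError(MultipatchError):
    """Stage counts unusable for maximum-likelihood calibration."""


class ConfigError(MultipatchError):
    """Invalid run configuration."""
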