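"""Exception hierarchy for the cost-utility model."""


class TransoralCUAError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TransoralCUAError, ValueError):
    """A distribution or model parameter is outside its admissible domain."""


class InfeasibleMomentsError(InvalidParameterError):
    """Requested moments cannot be represented by the target family
    (e.g. beta variance >= mean*(1-mean))."""


class SchemaError(TransoralCUAError, ValueError):
    """A parameter table / configuration file violates the expected schema."""


class CalibrationError(TransoralCUAError, RuntimeError):
    """A calibration target cannot be bracketed or reached."""


class ModelSpecificationError(TransoralCUAError, ValueError):
    """A transition structure is internally inconsistent (e.g. a row of
    outflow probabilities exceeding 1). Never silently renormalised."""
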