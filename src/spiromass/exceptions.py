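"""Exception hierarchy shared by all analysis stages."""


class SpiromassError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SpiromassError, ValueError):
    """A physical parameter is outside its valid domain (e.g. pitch <= 0)."""


class InconsistentInputsError(SpiromassError, ValueError):
    """Inputs are individually valid but mutually impossible
    (e.g. computed water volume exceeding the cell volume)."""


class CalibrationError(SpiromassError, RuntimeError):
    """The internal-standard calibration could not be established."""


class FitError(SpiromassError, RuntimeError):
    """A least-squares fit failed or the data do not support the model."""
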