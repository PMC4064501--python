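"""Exception hierarchy used across the package."""


class AdaptkError(Exception):
    """Base class for all package errors."""


class FormatError(AdaptkError):
    """Input file does not match the expected schema."""


class DataError(AdaptkError):
    """Input file is well-formed but the data violate a contract."""


class AlignmentError(AdaptkError):
    """Identifiers of related inputs cannot be aligned."""


class ParameterError(AdaptkError):
    """An argument is outside its allowed range."""


class EstimationError(AdaptkError):
    """A model could not be estimated from the data supplied."""


class ConvergenceError(EstimationError):
    """An iterative fit failed to converge."""
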