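"""Exception hierarchy shared across the assay pipelines."""


class AgequantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AgequantError, ValueError):
    """A simulation or analysis parameter violates its preconditions."""


class InvalidInputError(AgequantError, ValueError):
    """Input data violate the contract of an operation."""


class EstimationError(AgequantError, RuntimeError):
    """Estimation impossible for the given record (e.g. no usable plates)."""


class UndefinedRatioError(AgequantError, ArithmeticError):
    """A normalising denominator is zero, making a ratio undefined."""


class SegmentationError(AgequantError, RuntimeError):
    """Automatic trace segmentation failed; manual boundaries required."""


class SelectionError(AgequantError, RuntimeError):
    """No candidate satisfied the selection criterion (e.g. no converged fit)."""


class InvalidDesignError(AgequantError, ValueError):
    """Experimental design unsuitable for the requested comparison."""


class EmptyScreenError(AgequantError, RuntimeError):
    """Artefact filtering removed every scoreable position."""


class CalibrationError(AgequantError, RuntimeError):
    """Per-sample calibration impossible (too few finite values)."""
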