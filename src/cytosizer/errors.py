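"""Exception hierarchy for the sizing pipeline.

Errors are deliberately fine-grained so that batch drivers can distinguish
"this frame had no segmentable particle" (skip and log) from genuine
programming or configuration mistakes (fail fast).
"""


class CytosizerError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CytosizerError, ValueError):
    """Raised when input data violates a precondition (empty image, bad sizes)."""


class InvalidParameterError(CytosizerError, ValueError):
    """Raised when a configuration parameter is out of its valid domain."""


class NoParticleError(CytosizerError):
    """Raised when a frame contains no segmentable foreground component."""


class DegenerateDesignError(CytosizerError):
    """Raised when a regression design matrix is singular (too few distinct x)."""


class UndefinedMetricError(CytosizerError):
    """Raised when a metric has no defined value (e.g. IoU of two empty masks)."""


class ModelParseError(CytosizerError, ValueError):
    """Raised when a persisted model file is malformed."""


class CalibrationFailedError(CytosizerError):
    """Raised when too few bead classes survive segmentation to fit a model."""
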