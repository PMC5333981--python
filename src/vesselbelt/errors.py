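"""Exception hierarchy shared across the package."""


class VesselBeltError(Exception):
    """Base class for package errors."""


class GeometryError(VesselBeltError):
    """Degenerate or invalid geometry (zero-area polygon, self-intersection)."""


class ConfigurationError(VesselBeltError):
    """Inconsistent user-supplied parameters (belt wider than tumor, singular stain matrix, ...)."""


class DegenerateInputError(VesselBeltError):
    """Input that carries no usable signal (constant image channel, empty pattern)."""


class NotEvaluableError(VesselBeltError):
    """A sample that cannot be analyzed (too few vessels in the tumor ROI)."""


class LabelError(KeyError, VesselBeltError):
    """Requested ROI label is absent from the ROI set."""
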