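"""Exception hierarchy shared across the package."""


class HyperskinError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HyperskinError, ValueError):
    """An input violates a documented precondition (shape, range, ordering)."""


class ConfigurationError(HyperskinError, RuntimeError):
    """A bundled resource is missing or corrupt."""


class DegenerateIlluminantError(ValidationError):
    """The illuminant integrates to zero luminance; XYZ scaling is undefined."""


class InsufficientDataError(ValidationError):
    """Too few observations to identify the requested model."""


class ModelIncompleteError(HyperskinError, RuntimeError):
    """A fitted artifact is missing a component required by the operation."""


class ProvenanceError(ValidationError):
    """A colorimetric value with the wrong provenance tag was passed."""


class EmptyRegionError(ValidationError):
    """A region-of-interest mask selects no pixels."""
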