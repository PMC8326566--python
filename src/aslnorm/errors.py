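"""Exception types shared across the package."""


class AslNormError(Exception):
    """Base class for all package errors."""


class GeometryError(AslNormError):
    """Two volumes that must share a grid do not."""


class DimensionalityError(AslNormError):
    """Input volume is not a scalar 3-D image."""


class ParameterError(AslNormError):
    """A parameter is outside its admissible range."""


class DegenerateInputError(AslNormError):
    """Input is structurally valid but degenerate (empty mask, all-zero image, rank-deficient fit)."""


class InputError(AslNormError):
    """A required input is missing or unusable."""
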