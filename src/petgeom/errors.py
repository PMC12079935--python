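"""Exception hierarchy shared across the package."""


class PetgeomError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PetgeomError, ValueError):
    """A parameter value is outside its documented domain."""


class InvalidInputError(PetgeomError, ValueError):
    """Input data violates a precondition (empty mask, single-class labels, ...)."""


class DegenerateLesionError(InvalidInputError):
    """The seed voxel cannot anchor a segmentation (e.g. non-positive uptake)."""


class FormatError(PetgeomError, IOError):
    """A file exists but does not have the expected structure."""
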