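"""Exception hierarchy used across the package."""


class AortamorphError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AortamorphError, ValueError):
    """An input violates a documented contract (invariant or precondition)."""


class VolumeFormatError(AortamorphError, ValueError):
    """A file cannot be interpreted as a 3D integer label volume."""


class ShapeMismatchError(ValidationError):
    """Two volumes that must share grid shape and spacing do not."""


class ZeroVarianceError(ValidationError):
    """Paired differences are all identical; the t statistic is undefined."""


class PatientExcluded(AortamorphError):
    """No slice of this patient passed the three-region filter."""
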