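"""Exception hierarchy for the light-curtain shoot-phenotyping pipeline."""


class LCShootError(Exception):
    """Base class for all package errors."""


class FormatError(LCShootError):
    """A scan file is malformed or contains non-binary data after thresholding."""


class MetadataError(LCShootError):
    """A mandatory sidecar metadata key is missing or invalid."""


class ValidationError(LCShootError):
    """A domain object violates one of its invariants."""


class PotEdgeNotFoundError(LCShootError):
    """No row pair satisfies the pot upper-edge rule."""


class IncompleteStackError(LCShootError):
    """A multi-view statistic was requested on a stack missing view angles."""


class UndefinedStatisticError(LCShootError):
    """The reference mean is zero, so a relative deviation is undefined."""


class FitError(LCShootError):
    """A calibration fit is impossible (too few points or zero variance)."""


class CalibrationMisuseError(LCShootError):
    """A calibration model was applied at a scanning speed it was not fitted for."""


class CompositionError(LCShootError):
    """Two silhouettes with incompatible geometry cannot be composed."""


class GenerationError(LCShootError):
    """The synthetic-plant sampler could not satisfy the requested ranges."""


class LayoutError(LCShootError):
    """Pots placed on the virtual bench overlap."""
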