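"""Exception hierarchy shared across the pipeline."""


class SaltSpecError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SaltSpecError):
    """On-disk artifact is malformed (missing sidecar, bad table layout...)."""


class VocabularyError(SaltSpecError):
    """A band label is not in the controlled band vocabulary."""


class BandMismatchError(SaltSpecError):
    """Two images that must share a band label do not."""


class ShapeMismatchError(SaltSpecError):
    """Two grids that must share a shape do not."""


class MaskError(SaltSpecError):
    """Empty or otherwise unusable plant mask."""


class UndefinedStatisticError(SaltSpecError):
    """A statistic (CV, correlation, index) is undefined for the input."""


class SegmentationError(SaltSpecError):
    """Plant segmentation produced no foreground."""


class ConfigSchemaError(SaltSpecError):
    """Run-configuration key unknown or of the wrong type."""


class SplitError(SaltSpecError):
    """Invalid train/validation split request or pot leakage."""


class AllocationError(SaltSpecError):
    """Infeasible or inconsistent stem-kernel allocation."""
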