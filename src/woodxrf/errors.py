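"""Exception hierarchy for the woodxrf pipeline."""


class WoodXRFError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WoodXRFError):
    """A spectrum or manifest file does not follow the documented layout."""


class CalibrationError(WoodXRFError):
    """Energy calibration is missing, inconsistent, or non-uniform."""


class ManifestError(WoodXRFError):
    """Manifest violates its contract (duplicates, inconsistent labels)."""


class DegenerateSpectrumError(WoodXRFError):
    """A spectrum with zero total counts cannot be normalised."""


class CoverageError(WoodXRFError):
    """The feature grid and the detector energy range do not overlap."""


class ConfigurationError(WoodXRFError):
    """Invalid or contradictory configuration values."""


class ArchitectureError(WoodXRFError):
    """The network cannot be built for the requested input size."""


class StratificationError(WoodXRFError):
    """A class has too few rows or sample groups to split."""


class GridMismatchError(WoodXRFError):
    """Features are not on the grid the classifier was trained on."""


class IntegrityError(WoodXRFError):
    """A persisted model artifact is incomplete or corrupted."""
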