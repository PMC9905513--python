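"""Exception types shared across the toolkit."""


class ArtefactScanError(Exception):
    """Base class for all toolkit errors."""


class ImageFormatError(ArtefactScanError):
    """Raised when an image file cannot be read or has an unsupported layout."""


class DegenerateTemplateError(ArtefactScanError, ValueError):
    """Template has zero variance; correlation is undefined for it."""


class NoDetectionsError(ArtefactScanError, ValueError):
    """A threshold sweep produced no detections at any threshold."""


class UndefinedEfficiencyError(ArtefactScanError, ValueError):
    """Efficiency requested with zero detected areas."""


class InsufficientDataError(ArtefactScanError, ValueError):
    """Not enough observations to compute the requested statistic."""


class GeometryError(ArtefactScanError, ValueError):
    """Tile-mosaic geometry is internally inconsistent."""


class PlacementError(ArtefactScanError, RuntimeError):
    """Synthetic plants could not be placed within the attempt budget."""


class FeasibilityError(ArtefactScanError, RuntimeError):
    """Requested point density is infeasible under the minimum separation."""


class LowContrastWarning(UserWarning):
    """A colour class matched almost no pixels; detection may be unreliable."""
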