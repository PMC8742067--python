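"""Exception hierarchy for the plate-imaging pipeline."""


class DepthPlateError(Exception):
    """Base class for all pipeline errors."""


class PlateNotFound(DepthPlateError):
    """No circle in the Hough accumulator cleared the vote threshold."""


class DegenerateGeometry(DepthPlateError):
    """Plate geometry unusable (e.g. non-positive radius)."""


class EmptyBurst(DepthPlateError):
    """A depth-frame burst contained zero frames."""


class ShapeMismatch(DepthPlateError):
    """Arrays that must be co-registered have different shapes."""


class NoTablePixels(DepthPlateError):
    """A height-map row exposes no table region for tilt correction."""


class DegenerateSeeds(DepthPlateError):
    """Too few seed pixels to fit a color model for graph cut."""


class ConfigError(DepthPlateError):
    """Invalid model or pipeline configuration."""


class DataError(DepthPlateError):
    """Training data malformed (e.g. image without a mask)."""


class ZeroReference(DepthPlateError):
    """Reference (full-portion) quantity is zero; ratios undefined."""


class EmptyImage(DepthPlateError):
    """Metric requested on an image with zero pixels."""


class NoFoodInTarget(DepthPlateError):
    """Recall undefined: the target mask contains no food pixels."""


class EmptyUnion(DepthPlateError):
    """IOU undefined: both masks are empty."""


class EmptyList(DepthPlateError):
    """Summary statistics requested on an empty collection."""


class SpecError(DepthPlateError):
    """Synthetic scene specification invalid (e.g. item outside plate)."""


class FormatError(DepthPlateError):
    """On-disk frame or mask violates the format contract."""
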