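"""Exception hierarchy shared across the package."""


class EchomorphError(Exception):
    """Base class for all package errors."""


class CalibrationError(EchomorphError):
    """Pixel spacing missing: no DICOM PixelSpacing tag and no override."""


class UnsupportedFormatError(EchomorphError):
    """Input image is not single-channel grayscale, or file type unknown."""


class RoiFormatError(EchomorphError):
    """ROI file malformed (fewer than 3 vertices, bad structure)."""


class RoiGeometryError(EchomorphError):
    """ROI polygon is self-intersecting or otherwise not simple."""


class DegenerateRoiError(EchomorphError):
    """Polygon captures no pixel centers (falls between the raster grid)."""


class DegenerateAxesError(EchomorphError):
    """Mask too small for a principal-axis decomposition."""


class DegenerateSampleError(EchomorphError):
    """A statistical routine received a constant / zero-variance sample."""


class AnalysisSkipped(EchomorphError):
    """Raised when a separability analysis lacks the minimum class sizes."""
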