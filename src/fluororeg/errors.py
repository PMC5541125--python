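"""Exception hierarchy for the registration pipeline.

Every stage raises a subclass of :class:`FluororegError` so callers (and the
experiment driver, which records per-seed failures and continues) can catch
pipeline problems without masking programming errors.
"""


class FluororegError(Exception):
    """Base class for all pipeline errors."""


class ProjectionError(FluororegError):
    """A 3D point lies at or behind the X-ray source (z <= 0 in camera frame)."""


class CalibrationError(FluororegError):
    """Bead segmentation / grid coverage / polynomial fit failure."""


class MatchingError(CalibrationError):
    """Ambiguous or non-bijective bead-to-lattice assignment."""


class DetectionError(FluororegError):
    """Fewer fiducial features found than required."""


class LabelingError(DetectionError):
    """Detected features could not be unambiguously labelled."""


class DegenerateConfigurationError(FluororegError):
    """No perspective-3-point candidate passes the pin-tip gate."""


class ConvergenceError(FluororegError):
    """An iterative optimisation failed to converge."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class SegmentationError(FluororegError):
    """Contour segmentation failed (e.g. mostly occluded edge)."""


class RenderError(FluororegError):
    """Synthetic scene does not fit the field of view."""


class MeshError(FluororegError):
    """Mesh input invalid (open surface, degenerate cut, parse failure)."""


class ValidationError(FluororegError):
    """Serialized object fails its invariants on read."""
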