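"""Exception hierarchy shared across the pipeline.

Stage errors carry enough context (file names, feasible ranges) that a CLI
user can fix the input without reading the source.
"""


class PlacidoError(Exception):
    """Base class for all package errors."""


class FormatError(PlacidoError, ValueError):
    """Input image/array has an unsupported layout (e.g. channel count)."""


class ParameterError(PlacidoError, ValueError):
    """A processing parameter is outside its valid range."""


class BoundaryError(PlacidoError, ValueError):
    """A crop window or region does not fit inside the image."""


class EmptyROIError(PlacidoError, ValueError):
    """The pupil region does not intersect the image."""


class EmptyInputError(PlacidoError, ValueError):
    """A container decoded to zero frames, or every row was excluded."""


class FrameRangeError(PlacidoError, IndexError):
    """Requested post-blink time lies beyond the recording.

    Models subjects who could not keep the eye open for the full measurement;
    ``max_time`` reports the largest available post-blink offset in seconds.
    """

    def __init__(self, message: str, max_time: float):
        super().__init__(message)
        self.max_time = max_time


class CalibrationError(PlacidoError, ValueError):
    """A grade boundary cannot be calibrated (empty side, unknown metric)."""


class InputError(PlacidoError, ValueError):
    """Statistical routine received malformed input (single class, length mismatch)."""
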