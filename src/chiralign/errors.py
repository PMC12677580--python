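"""Exception types raised across the pipeline."""


class ChiralignError(Exception):
    """Base class for all package-specific errors."""


class FiducialMissingError(ChiralignError):
    """The "F" registration mark could not be located in the image."""


class ImageFlippedError(ChiralignError):
    """The "F" mark matches its mirror image better than itself.

    A mirrored field of view inverts every clockwise/counter-clockwise
    call, so analysis must abort rather than silently report the wrong
    chirality.
    """


class OutOfBoundsError(ChiralignError, ValueError):
    """A requested crop window extends beyond the image."""


class InvalidGeometryError(ChiralignError, ValueError):
    """A scene layout is infeasible (overlaps or exceeds the canvas)."""


class UndefinedMeanError(ChiralignError):
    """The mean resultant length is (numerically) zero, so the circular
    mean direction is undefined."""


class CIUndefinedError(ChiralignError):
    """The confidence interval for the mean direction cannot be formed."""
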