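"""Exception hierarchy for pipeline contract violations."""


class RotovolError(Exception):
    """Base class for all pipeline errors."""


class DegenerateImageError(RotovolError, ValueError):
    """Raised when an image is constant and a data-driven threshold or
    correlation is undefined."""


class NoCellError(RotovolError, ValueError):
    """Raised when a binarized image contains no foreground component."""


class InsufficientFramesError(RotovolError, ValueError):
    """Raised when a video is shorter than the requested rotation period."""


class AperiodicSignalError(RotovolError, ValueError):
    """Raised when a correlation series has no usable interior peaks."""


class LostFeatureError(RotovolError, ValueError):
    """Raised when template matching falls below the confidence floor."""


class DivergenceError(RotovolError, RuntimeError):
    """Raised when training produces a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")


class EmptyGLCMError(RotovolError, ValueError):
    """Raised when no valid voxel pairs fall inside the co-occurrence mask."""


class EmptySurfaceError(RotovolError, ValueError):
    """Raised when an isovalue lies outside the volume's intensity range."""


class UndefinedStatisticError(RotovolError, ValueError):
    """Raised for degenerate statistics: zero-mean CV, zero-variance
    paired differences, undefined correlations."""
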