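"""Exception hierarchy shared by all rsdfseg modules.

The CLI maps these onto distinct exit codes: configuration problems -> 2,
I/O problems -> 3, numerical failures during evolution -> 4.
"""


class RsdfsegError(Exception):
    """Base class for all rsdfseg errors."""


class InvalidParameterError(RsdfsegError, ValueError):
    """A parameter violates its documented constraint (e.g. the CFL bound)."""


class InvalidInitializationError(InvalidParameterError):
    """Initial contour is empty, fills the whole domain, or leaves the grid."""


class ImageIOError(RsdfsegError, OSError):
    """An input image or mask could not be read or written."""


class ShapeMismatchError(RsdfsegError, ValueError):
    """Two fields that must share a grid have different shapes."""


class OneSidedRegionError(RsdfsegError, RuntimeError):
    """The contour collapsed: one region's effective pixel count vanished."""


class DegenerateDiscriminantError(RsdfsegError, RuntimeError):
    """Region means coincide, so the discriminant ratio is undefined."""


class NumericalBlowupError(RsdfsegError, RuntimeError):
    """Non-finite values appeared in the level-set update."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class UndefinedScoreError(RsdfsegError, ValueError):
    """A similarity score is undefined (e.g. Jaccard of two empty masks)."""
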