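"""Exception types shared across the package."""


class AdversegError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AdversegError, ValueError):
    """A configuration or specification object violates its invariants.

    ``field`` names the offending field when known.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        if field is not None:
            message = f"{field}: {message}"
        super().__init__(message)


class ShapeError(AdversegError, ValueError):
    """Array shapes are inconsistent with an operation's contract."""


class UnknownColorError(AdversegError, ValueError):
    """A mask PNG contains a color not present in the label scheme."""

    def __init__(self, color, position):
        self.color = tuple(int(v) for v in color)
        self.position = tuple(int(v) for v in position)
        super().__init__(
            f"unknown mask color {self.color} at pixel (row, col) = {self.position}"
        )


class UnsupportedImageError(AdversegError, ValueError):
    """An input image has a mode/bit depth the reader does not accept."""


class TrainingDivergedError(AdversegError, RuntimeError):
    """A non-finite loss was produced; ``step`` is the 0-based step index."""

    def __init__(self, step: int, what: str):
        self.step = step
        super().__init__(f"non-finite {what} at training step {step}")
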