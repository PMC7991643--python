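"""Typed exceptions shared across the package.

Degenerate numerical situations (constant images, zero background
variance) raise typed errors instead of silently propagating NaN into
aggregate tables.
"""


class VirtustainError(Exception):
    """Base class for all package errors."""


class ValidationError(VirtustainError, ValueError):
    """Invalid argument values (negative variances, bad proportions...)."""


class ShapeError(VirtustainError, ValueError):
    """Mismatched or unsupported array shapes."""


class UndefinedStatisticError(VirtustainError, ArithmeticError):
    """A statistic is undefined for this input (constant image, zero
    background variance)."""


class PlacementError(VirtustainError, RuntimeError):
    """Cell placement failed within the rejection-sampling budget."""


class FormatError(VirtustainError, ValueError):
    """Unsupported file format or schema version."""


class TrainingDivergenceError(VirtustainError, RuntimeError):
    """Loss became non-finite during training."""

    def __init__(self, iteration: int, message: str | None = None):
        self.iteration = iteration
        super().__init__(message or f"non-finite loss at iteration {iteration}")


class FitFailureError(VirtustainError, RuntimeError):
    """A model fit could not be performed (e.g. non-decaying ACF head)."""
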