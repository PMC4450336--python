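"""Exception hierarchy shared by all stages."""


class ShrinkregError(Exception):
    """Base class for all package errors."""


class ParameterError(ShrinkregError, ValueError):
    """An argument is outside its valid domain (e.g. non-positive spacing)."""


class GridCompatibilityError(ShrinkregError, ValueError):
    """Two gridded objects were combined voxelwise but their grids differ."""


class FormatError(ShrinkregError, ValueError):
    """A file does not satisfy the reader's structural requirements."""


class LookupError_(ShrinkregError, KeyError):
    """A named structure or key is absent."""


class DegenerateInputError(ShrinkregError, ValueError):
    """Input is structurally valid but the operation is undefined on it
    (empty bone overlap, all-air tumor region, ...)."""


class NumericalFailureError(ShrinkregError, ArithmeticError):
    """Non-finite values appeared during iteration; carries the iteration index."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
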