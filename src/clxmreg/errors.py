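"""Exception hierarchy.

Each leaf maps to a distinct CLI exit code so that batch callers can
distinguish bad inputs from degenerate landmark geometry from optimiser
failure (see :mod:`clxmreg.cli`).
"""


class ClxmError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class FormatError(ClxmError):
    """Unreadable, truncated or structurally invalid image/table file."""

    exit_code = 3


class MetadataError(ClxmError):
    """Required physical-scale metadata (pixel size) missing and not overridden."""

    exit_code = 3


class InputError(ClxmError):
    """Arguments violate an operation's preconditions (shape mismatch, empty stack ...)."""

    exit_code = 3


class DegenerateInputError(InputError):
    """Input on which the operation is mathematically undefined (e.g. Otsu of a flat image)."""


class PackingError(ClxmError):
    """Droplet placement could not satisfy the separation constraints."""

    exit_code = 3


class DegenerateGeometryError(ClxmError):
    """Too few / collinear landmarks for a transform fit."""

    exit_code = 4


class ConvergenceError(ClxmError):
    """Iterative refinement failed to converge; carries the best estimate found."""

    exit_code = 5

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class ProtocolError(ClxmError):
    """Leave-one-out protocol preconditions violated (e.g. fewer than 4 landmarks)."""

    exit_code = 6
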