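"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`MPContourError`, so callers (and the CLI) can distinguish
categorized failures from programming errors.
"""

from __future__ import annotations


class MPContourError(Exception):
    """Base class for all errors raised by mpcontour."""


class ParameterError(MPContourError, ValueError):
    """A parameter violates its contract (sign, range, stability bound)."""


class ImageFormatError(MPContourError, ValueError):
    """An input image has the wrong shape, channel count or dtype."""


class NumericalStabilityError(MPContourError, ArithmeticError):
    """NaN/Inf appeared during an iterative scheme.

    The message names the offending step.
    """


class DegenerateRegionError(MPContourError):
    """A sub-region became (effectively) empty, degenerating the two-phase split.

    Attributes
    ----------
    side : str
        ``"inner"`` or ``"outer"`` -- which region emptied.
    """

    def __init__(self, side: str, message: str | None = None):
        self.side = side
        super().__init__(message or f"{side} region is empty; two-phase formulation degenerates")


class ConsistencyError(MPContourError, ValueError):
    """Masks or results violate a structural invariant (e.g. nesting)."""


class PipelineError(MPContourError):
    """A lower-level error occurred during a specific segmentation pass.

    Attributes
    ----------
    pass_index : int
        Zero-based index of the pass in which the error occurred.
    """

    def __init__(self, pass_index: int, message: str):
        self.pass_index = pass_index
        super().__init__(f"pass {pass_index}: {message}")
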