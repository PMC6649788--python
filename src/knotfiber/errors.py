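"""Exception types shared across knotfiber modules."""


class KnotfiberError(Exception):
    """Base class for all knotfiber errors."""


class InvalidParametersError(KnotfiberError, ValueError):
    """Model parameters violate a geometric or statistical precondition."""


class SamplingFailureError(KnotfiberError, RuntimeError):
    """The Monte Carlo sampler made no progress (jammed parameters)."""


class DegenerateAxisError(KnotfiberError, ValueError):
    """Crankshaft rotation axis is undefined (coincident pivot beads)."""


class DegenerateProjectionError(KnotfiberError, RuntimeError):
    """Projection direction produced a non-generic diagram; redraw needed."""


class ClassificationError(KnotfiberError, RuntimeError):
    """Knot classification exhausted its projection redraw budget."""


class UndefinedWritheError(KnotfiberError, ValueError):
    """Exact writhe is undefined (intersecting segment pair)."""


class UndefinedAutocorrelationError(KnotfiberError, ValueError):
    """Autocorrelation time is undefined (constant series)."""


class ExtrapolationError(KnotfiberError, ValueError):
    """Calibration target lies outside the tabulated range."""


class NonMonotoneTableError(KnotfiberError, ValueError):
    """Calibration table is not monotone within its stated tolerance."""


class UndefinedConditionalError(KnotfiberError, ValueError):
    """Conditional knot probability undefined (zero supercoiled fraction)."""


class MalformedFrameError(KnotfiberError, ValueError):
    """A multi-frame XYZ file contains a malformed frame."""

    def __init__(self, frame_index, message):
        self.frame_index = frame_index
        super().__init__(f"frame {frame_index}: {message}")
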