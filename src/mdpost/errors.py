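"""Exception hierarchy shared across all analysis modules."""


class MdpostError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MdpostError):
    """A trajectory file could not be parsed; the message names the frame."""


class StructuralError(MdpostError):
    """Frames of one trajectory disagree in atom count or element ordering."""


class GeometryError(MdpostError):
    """Invalid cell geometry (singular matrix, missing bounding box, ...)."""


class SelectionError(MdpostError):
    """An atom selection is empty, out of range, or otherwise unusable."""


class ParameterError(MdpostError):
    """An analysis parameter is outside its valid range."""


class DegenerateSeriesError(MdpostError):
    """A time series has zero variance, so correlation analysis is undefined."""


class InsufficientDataError(MdpostError):
    """Too few samples/blocks to carry out the requested estimate."""


class NoMinimumError(MdpostError):
    """g(r) has no detectable first minimum in the searched range."""


class UnwrapError(MdpostError):
    """A per-frame displacement exceeds half the cell; unwrapping is ambiguous."""
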