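"""Exception types shared across the package."""


class RangeshiftError(Exception):
    """Base class for package errors."""


class MissingLayerError(RangeshiftError, KeyError):
    """A named predictor layer is absent from the stack."""


class EmptySupportError(RangeshiftError, ValueError):
    """A sampling surface has no cells with positive probability."""


class DegenerateGeometryError(RangeshiftError, ValueError):
    """Too few or collinear points to build a planar hull."""


class GridAlignmentError(RangeshiftError, ValueError):
    """Two rasters that must share a grid do not."""
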