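"""Exception hierarchy for svdquant.

Every anticipated failure mode raises a subclass of :class:`SvdQuantError`
so callers can distinguish pipeline faults from programming errors.
"""


class SvdQuantError(Exception):
    """Base class for all svdquant errors."""


class FormatError(SvdQuantError):
    """A file could not be parsed as the named image format."""


class DimensionalityError(FormatError):
    """An image does not have exactly three spatial dimensions."""


class GridMismatchError(SvdQuantError):
    """Two volumes/masks expected on one grid live on different grids."""


class TransformError(SvdQuantError):
    """An affine transform is singular or otherwise unusable."""


class SegmentationError(SvdQuantError):
    """A segmentation stage produced an empty or degenerate result."""


class DegenerateContrastError(SvdQuantError):
    """An image has no usable contrast inside the requested domain."""


class ConfigurationError(SvdQuantError):
    """Inconsistent rules or parameters supplied by the caller."""


class ParameterError(SvdQuantError):
    """A numeric parameter is outside its legal range."""


class ValidationError(SvdQuantError):
    """An input value violates its documented range or invariant."""


class InclusionError(SvdQuantError):
    """A mask expected to be a subset of another is not."""
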