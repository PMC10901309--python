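"""Exception hierarchy for the mtmkin package."""


class MtmkinError(Exception):
    """Base class for all package errors."""


class SchemaError(MtmkinError):
    """Input file is missing required columns or has an unusable layout."""


class MalformedFrameError(MtmkinError):
    """A frame does not carry exactly one row per pose landmark."""


class FrameGapError(MtmkinError):
    """Frame indices are not contiguous from zero."""


class CatalogueError(MtmkinError):
    """An annotation names an item outside the 10-item MTM catalogue."""


class IntervalError(MtmkinError):
    """An event interval is empty, inverted, or outside the video."""


class InvalidCoordinateError(MtmkinError):
    """A coordinate is non-finite where a finite value is required."""


class DegenerateGeometryError(MtmkinError):
    """Geometry is degenerate (horizontal body axis, zero body length, ...)."""


class InvalidFrameError(MtmkinError):
    """A frame lacks landmarks required for the requested computation."""


class NoDataError(MtmkinError):
    """No valid frames (or videos) remain to aggregate."""


class DegenerateSampleError(MtmkinError):
    """A statistical sample is constant or otherwise degenerate."""


class UndefinedCorrelationError(MtmkinError):
    """Correlation is undefined (a constant input vector)."""


class InsufficientDataError(MtmkinError):
    """Too few observations for the requested statistic."""


class ScheduleError(MtmkinError):
    """A synthetic event schedule is inconsistent (overlap, out of range)."""


class PipelineError(MtmkinError):
    """A fatal end-to-end pipeline condition (e.g. every video excluded)."""
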