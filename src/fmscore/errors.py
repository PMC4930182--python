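"""Exception hierarchy shared across the package."""


class FMSError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FMSError):
    """A recording or table file could not be parsed."""


class ValidationError(FMSError):
    """A parsed object violates a structural invariant."""


class SchemaError(FMSError):
    """A tabular file is missing mandatory columns."""


class NoMotionError(FMSError):
    """Motion clipping found no frame above the displacement threshold."""


class DegenerateSkeletonError(FMSError):
    """Body-segment lengths are too small to normalize against."""


class DegenerateMotionError(FMSError):
    """A trajectory has no measurable displacement (zero length scale)."""


class InsufficientDataError(FMSError):
    """Too few frames for the requested numerical operation."""


class FeatureError(FMSError):
    """A kinematic feature could not be computed for a recording."""


class ContractError(FMSError):
    """Caller violated an interface contract (shape, names, codomain)."""


class RankError(FMSError):
    """Requested more principal components than the data rank supports."""
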