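"""Exception hierarchy shared across the package."""


class TendonMriError(Exception):
    """Base class for all package-specific errors."""


class InputError(TendonMriError):
    """A precondition on user-supplied values was violated."""


class FormatError(TendonMriError):
    """An input file or array does not have the expected layout."""


class GeometryError(TendonMriError):
    """A geometric construction (ROI placement, circle bounds) is infeasible."""


class ParameterError(TendonMriError):
    """Phantom or segmentation parameters are inconsistent."""


class UndefinedResultError(TendonMriError):
    """The requested quantity is mathematically undefined for this input."""
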