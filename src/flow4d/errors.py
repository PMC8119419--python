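"""Exception hierarchy shared across the package."""


class Flow4DError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(Flow4DError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidOperationError(Flow4DError, ValueError):
    """An operation was requested on an object that does not support it."""


class GridTooLargeError(Flow4DError):
    """A requested voxel grid exceeds the configured extent budget."""


class SamplingExhaustedError(Flow4DError):
    """Rejection sampling failed to find an admissible sample."""


class UndefinedMetricError(Flow4DError, ValueError):
    """A metric was requested on data for which it is undefined (e.g. empty mask)."""


class FormatError(Flow4DError, ValueError):
    """A file is missing required structure or metadata."""
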