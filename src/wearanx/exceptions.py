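"""Exception types shared across the package."""


class WearanxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(WearanxError, ValueError):
    """A parameter violates its documented precondition."""


class InvalidInputError(WearanxError, ValueError):
    """An input series/table violates its documented contract."""


class InvalidPlanError(WearanxError, ValueError):
    """A session plan has overlapping or non-contiguous intervals."""


class DegenerateRangeError(WearanxError, ValueError):
    """A series is constant where a nonzero range is required."""


class DegenerateInputError(WearanxError, ValueError):
    """An input is structurally valid but carries no information."""


class SchemaError(WearanxError, ValueError):
    """Feature schema mismatch between a fitted model and new data."""


class StratificationError(WearanxError, ValueError):
    """A cross-validation fold cannot contain both classes."""


class NotFittedError(WearanxError, RuntimeError):
    """An estimator method requiring a prior fit was called unfitted."""
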