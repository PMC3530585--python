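"""Exception hierarchy for budfate."""


class BudfateError(Exception):
    """Base class for all budfate errors."""


class DataFormatError(BudfateError):
    """A tabular input does not have the expected columns/layout."""


class DataValidationError(BudfateError):
    """One or more rows violate the tree-year record invariants."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class TransformError(BudfateError):
    """The logit transform is undefined for a record (P_LS at 0 or 1)."""


class SingularDesignError(BudfateError):
    """The regression design matrix is rank deficient."""


class UndefinedCriticalValueError(BudfateError):
    """PI* = -c/e is undefined (interaction coefficient absent or zero)."""


class DegenerateDataError(BudfateError):
    """Too many bootstrap resamples produced rank-deficient designs."""


class UndefinedRSquaredError(BudfateError):
    """R^2 is undefined because the response has zero total sum of squares."""
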