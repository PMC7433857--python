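"""Typed errors raised by scoring and statistics operations."""


class SemlossError(Exception):
    """Base class for all package errors."""


class NoMissedItemsError(SemlossError):
    """Spontaneous naming was perfect: the two proportion scores are undefined."""

    reason_code = "no-missed-items"


class UndefinedRatioError(SemlossError):
    """Naming and MMSE are both zero, so the naming/(naming+MMSE) ratio is undefined."""

    reason_code = "undefined-ratio"


class InvariantViolationError(SemlossError):
    """Input violates a record invariant (e.g. cued naming below spontaneous naming)."""

    reason_code = "invariant-violation"


class DegenerateVarianceError(SemlossError):
    """Within-group variance is zero; the F statistic is undefined."""

    reason_code = "degenerate-variance"


class UndefinedCorrelationError(SemlossError):
    """At least one variable is constant; Pearson's r is undefined."""

    reason_code = "undefined-correlation"


class RankDeficiencyError(SemlossError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message: str, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []
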