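"""Exception hierarchy shared across modules."""


class TrnAdaptError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(TrnAdaptError, ValueError):
    """A synthetic-study or pipeline specification violates its invariants."""


class DegenerateStatisticError(TrnAdaptError, ValueError):
    """A statistic is undefined on the given input.

    Raised e.g. for a relative connectivity drop when the baseline
    connectivity is zero, skewness of a zero-variance degree distribution,
    a Jaccard index of two empty sets, or a z-test with zero control
    variance.  Callers that can tolerate the degenerate case should catch
    this explicitly rather than receive a silent NaN.
    """


class MissingInputError(TrnAdaptError, ValueError):
    """A pipeline stage was requested without the input it needs."""
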