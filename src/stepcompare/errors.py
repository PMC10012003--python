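"""Exception hierarchy for stepcompare.

All package-specific failures derive from :class:`StepCompareError` so callers
can catch one base class at pipeline boundaries.
"""


class StepCompareError(Exception):
    """Base class for all stepcompare errors."""


class InvalidInputError(StepCompareError, ValueError):
    """A value violates an operation's preconditions."""


class InvalidRatingError(InvalidInputError):
    """A motivation rating falls outside the 1-5 scale."""


class ConfigError(StepCompareError, ValueError):
    """A study-design or simulation configuration is invalid."""


class ConsistencyError(StepCompareError, ValueError):
    """Records contradict each other (e.g. a selection not among the offers)."""


class UndefinedRatioError(StepCompareError, ZeroDivisionError):
    """A scale percentage cannot be formed because the anchor is zero."""


class SingularDesignError(StepCompareError, ValueError):
    """The fixed-effect design matrix is rank deficient.

    Carries the names of the offending (collinear) columns.
    """

    def __init__(self, collinear_terms):
        self.collinear_terms = list(collinear_terms)
        super().__init__(
            "fixed-effect design is rank deficient; collinear terms: "
            + ", ".join(self.collinear_terms)
        )
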