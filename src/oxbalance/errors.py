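"""Exception types shared across the package."""


class OxbalanceError(Exception):
    """Base class for package errors."""


class ConfigurationError(OxbalanceError):
    """A scoring table, model spec or cohort config is internally inconsistent."""


class CohortParseError(OxbalanceError):
    """A cohort file could not be parsed; carries row/column location."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        super().__init__(message)


class InsufficientDataError(OxbalanceError):
    """Too few non-missing values in a stratum to derive cutoffs."""


class DegenerateCutoffsError(OxbalanceError):
    """Derived tertile cutoffs collapsed (c1 == c2)."""


class SingularDesignError(OxbalanceError):
    """The regression design matrix is rank deficient; names the columns involved."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is singular; collinear columns: " + ", ".join(self.columns)
        )


class SeparationError(OxbalanceError):
    """Logistic fit failed to converge, typically from (quasi-)complete separation."""


class ZeroCellError(OxbalanceError):
    """A contingency-table cell is zero; a crude OR is undefined without a continuity correction."""
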