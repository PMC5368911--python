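"""Exception hierarchy shared across the package."""


class PleioscoreError(Exception):
    """Base class for all analysis errors raised by this package."""


class FormatError(PleioscoreError):
    """An input file is malformed (missing columns, unparseable fields)."""


class ConfigurationError(PleioscoreError):
    """A required analysis parameter is absent or inconsistent."""


class DomainError(PleioscoreError, ValueError):
    """A numeric argument lies outside the admissible domain."""


class CollinearityError(PleioscoreError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class SeparationError(PleioscoreError):
    """A logistic fit is (quasi-)separated and the MLE diverges."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class NumericalError(PleioscoreError):
    """An iterative numerical routine failed to converge."""
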