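"""Exception hierarchy shared across the package."""


class MetagaError(Exception):
    """Base class for all package errors."""


class SchemaError(MetagaError):
    """A required column or key is missing or malformed."""


class InputError(MetagaError):
    """Input file or data set unusable (empty, unreadable, wrong dialect)."""


class CoefficientError(MetagaError):
    """Coefficient or model-spec file violates panel term eligibility."""


class DegenerateInputError(MetagaError):
    """Data carries no information for the requested operation (e.g. a
    constant analyte in a regression screen)."""


class InsufficientDataError(MetagaError):
    """Too few complete records for the requested fit."""


class RankDeficientError(MetagaError):
    """Design matrix is rank deficient; carries the aliased term names."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(f"rank-deficient design; aliased terms: {self.aliased}")


class NoInformativeTermsError(MetagaError):
    """Term selection was given (or left with) an empty candidate set."""
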