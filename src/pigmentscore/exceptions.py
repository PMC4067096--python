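"""Exception hierarchy shared across the pipeline stages."""


class PigmentscoreError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PigmentscoreError, ValueError):
    """An input value violates a stated precondition."""


class ScoreDefinitionError(ValidationError):
    """A score-definition file is malformed or inconsistent."""


class MissingSnpError(PigmentscoreError, KeyError):
    """A score SNP is absent from the dosage matrix."""

    def __init__(self, rsids):
        self.rsids = list(rsids)
        super().__init__(f"score SNPs missing from dosage matrix: {', '.join(self.rsids)}")


class AlleleMismatchError(ValidationError):
    """The counted allele of a dosage column matches neither defined allele."""


class InsufficientDataError(ValidationError):
    """Too few observations to carry out the requested computation."""


class RankDeficiencyError(PigmentscoreError, ValueError):
    """The design matrix of a regression is rank deficient."""

    def __init__(self, message, columns=()):
        self.columns = list(columns)
        super().__init__(message)


class SeparationError(PigmentscoreError, RuntimeError):
    """A logistic fit failed to converge, consistent with complete separation."""


class SchemaError(PigmentscoreError, KeyError):
    """A table is missing required columns."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required columns: {', '.join(self.missing)}")


class DegenerateBinsError(ValidationError):
    """Quantile binning is impossible because all values coincide."""
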