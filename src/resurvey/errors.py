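"""Named exceptions raised across the pipeline.

Every validation failure carries enough context (plot, species, row, stage)
to locate the offending record in the input files.
"""


class ResurveyError(Exception):
    """Base class for all package errors."""


class SchemaError(ResurveyError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(ResurveyError):
    """A value violates a data-model invariant (e.g. negative cover)."""


class EmptyCommunityError(ValidationError):
    """A plot has no species with positive cover."""


class PairingError(ResurveyError):
    """Old/new plot pairing is not a bijection."""


class MetadataError(ResurveyError):
    """Inconsistent site metadata within a plot pair."""


class UndefinedError(ResurveyError):
    """A statistic is undefined for the given input (e.g. beta with one plot)."""


class DesignError(ResurveyError):
    """A model design matrix is rank-deficient or misaligned with the response."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics exceeded their thresholds."""


class CalibrationError(ResurveyError):
    """The synthetic generator cannot reach a requested turnover target."""


class InsufficientDataError(ResurveyError):
    """Too few observations for the requested computation."""
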