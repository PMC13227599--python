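"""Exception hierarchy for the dose-optimization pipeline.

Every stage raises a subclass of :class:`PrsOptError` so callers can catch
pipeline failures without masking programming errors.
"""


class PrsOptError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PrsOptError):
    """A required column or field is missing from an input table."""


class TableParseError(PrsOptError):
    """A cell could not be parsed; the message cites the offending row."""


class DoseRangeError(PrsOptError):
    """A dose lies outside the agent's tested [0, upper_bound] interval."""


class DegeneratePlateError(PrsOptError):
    """Vehicle signal does not exceed blank; viability is undefined."""


class StandardizationError(PrsOptError):
    """An agent column has zero variance under z-scoring."""


class SingularDesignError(PrsOptError):
    """The quadratic design matrix is rank deficient."""


class UnderdeterminedError(PrsOptError):
    """Fewer observations than design columns."""


class ExtrapolationError(PrsOptError):
    """Prediction requested outside the tested dose box without opt-in."""


class UndefinedStatisticError(PrsOptError):
    """A diagnostic statistic is undefined for the given residuals."""


class CVInfeasibleError(PrsOptError):
    """Every cross-validation training fold was rank deficient."""


class BootstrapUnstableError(PrsOptError):
    """Too many bootstrap resamples were rank deficient to report CIs."""


class UndefinedRatioError(PrsOptError):
    """Infiltration ratio undefined (zero baseline density)."""


class ConfigError(PrsOptError):
    """Run configuration is missing or inconsistent."""


class MixedBaselineError(PrsOptError):
    """A cohort mixes 9 dpf and 12 dpf baselines within one model fit."""
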