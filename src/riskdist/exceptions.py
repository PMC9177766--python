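"""Exception hierarchy for riskdist.

Every stage raises a subclass of :class:`RiskdistError` so that pipeline
orchestration can attach stage names while preserving the error class.
"""


class RiskdistError(Exception):
    """Base class for all riskdist errors."""


class SchemaError(RiskdistError):
    """A cohort file or frame does not match its variable specification."""


class IntegrityError(RiskdistError):
    """Cohort-level invariant violated (duplicate ids, missing hospital)."""


class ConfigError(RiskdistError):
    """Invalid configuration value or unknown configuration key."""


class FitError(RiskdistError):
    """A model fit could not be performed (degenerate data, rank issues)."""


class DegenerateOutcomeError(FitError):
    """Outcome has a single class where both are required."""


class ImputationError(RiskdistError):
    """Imputation impossible (e.g. a variable that is never observed)."""


class DesignError(RiskdistError):
    """Design matrix construction hit a missing value or unknown level."""


class PredictionError(RiskdistError):
    """A prediction-time input is missing a routinely-measured covariate."""


class PoolingError(RiskdistError):
    """Fits with incompatible structure cannot be pooled."""


class SplitError(RiskdistError):
    """Grouped cross-validation plan cannot be constructed."""


class EvaluationError(RiskdistError):
    """A score or calibration curve is undefined for the given inputs."""
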