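"""Exception types shared across the package."""


class NeurovulnError(Exception):
    """Base class for package errors."""


class ConfigError(NeurovulnError):
    """A cohort or study configuration value is invalid; names the field."""


class DegenerateScaleError(NeurovulnError):
    """A task metric has zero variance, so z-scores are undefined."""


class DegenerateTableError(NeurovulnError):
    """A contingency table has an empty row or column margin."""


class InferenceInstabilityError(NeurovulnError):
    """Too many bootstrap replicates failed for the resampling summary to be trusted."""


class MatchingError(NeurovulnError):
    """Propensity-score matching cannot proceed (e.g. an empty group)."""


class ValidationError(NeurovulnError):
    """A participant-level value is outside its documented range."""
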