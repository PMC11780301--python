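"""Exception hierarchy shared across the pipeline."""


class HealthGapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HealthGapError, ValueError):
    """An invalid configuration field; the message names the field."""


class ValidationError(HealthGapError, ValueError):
    """Input data violate a documented codebook or range constraint."""


class RankDeficiencyError(HealthGapError, ValueError):
    """Design matrix is rank deficient; the message lists collinear columns."""


class SeparationError(HealthGapError, RuntimeError):
    """Perfect separation in the propensity model."""
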