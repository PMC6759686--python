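"""Exception types shared across the package."""


class AcadScreenError(Exception):
    """Base class for package errors."""


class FormatError(AcadScreenError, ValueError):
    """A delimited-text or config file violates the expected layout."""


class ValidationError(AcadScreenError, ValueError):
    """Data values violate a contract (negative concentration, bad config...)."""


class FeatureLookupError(AcadScreenError, KeyError):
    """A feature name could not be resolved against the panel."""


class ConfigurationError(AcadScreenError, ValueError):
    """A rule or pipeline configuration references something unavailable."""
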