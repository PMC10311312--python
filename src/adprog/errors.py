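"""Exception hierarchy shared across the package."""


class AdprogError(Exception):
    """Base class for all package errors."""


class SchemaError(AdprogError):
    """A required column or feature is absent or misnamed."""


class IntegrityError(AdprogError):
    """Input data violates a structural invariant (duplicates, bad labels)."""


class ConfigError(AdprogError):
    """An invalid parameter or configuration value."""


class DegenerateDataError(AdprogError):
    """An operation would produce an empty or unusable result."""
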