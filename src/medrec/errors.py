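"""Exception hierarchy shared across the package."""


class MedrecError(Exception):
    """Base class for package errors."""


class StandoffParseError(MedrecError, ValueError):
    """A standoff annotation line could not be parsed."""


class IntegrityError(MedrecError, ValueError):
    """Data violates a structural invariant (offsets, relations, dates)."""


class SchemaError(MedrecError, ValueError):
    """A tabular input is missing mandatory columns."""


class ConfigError(MedrecError, ValueError):
    """An invalid configuration value or unknown dialect/mode."""


class UsageError(MedrecError, ValueError):
    """An operation was called with arguments that violate its contract."""
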