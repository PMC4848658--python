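"""Exception hierarchy for the bia_asm package."""


class BiaAsmError(Exception):
    """Base class for all package errors."""


class ValidationError(BiaAsmError, ValueError):
    """A subject record, field value or configuration failed validation."""


class SchemaError(ValidationError):
    """An input table is missing required columns."""


class InsufficientDataError(BiaAsmError, ValueError):
    """A statistic was requested on fewer pairs than it is defined for."""


class UndefinedCorrelationError(BiaAsmError, ValueError):
    """Pearson correlation requested on a constant series."""


class ConfigError(BiaAsmError, ValueError):
    """A generator or run configuration is internally inconsistent."""
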