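"""Exception hierarchy used across the package."""


class PainFusionError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PainFusionError, ValueError):
    """An invalid configuration value (filter band, kernel taus, class count...)."""


class SchemaError(PainFusionError, ValueError):
    """A tabular file does not match the expected column schema."""


class FormatError(PainFusionError, ValueError):
    """A file is structurally malformed (bad time base, missing sidecar...)."""


class ValidationError(PainFusionError, ValueError):
    """Runtime data fails an operation's precondition."""


class SegmentationError(PainFusionError, ValueError):
    """A requested analysis window does not fit inside the recording."""


class DataError(PainFusionError, ValueError):
    """Training/evaluation data is unusable (missing class, missing modality...)."""
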