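"""Exception and warning types shared across the package."""


class MsitmaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MsitmaError):
    """An invalid configuration value; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class ValidationError(MsitmaError):
    """A data object violates one of its invariants."""


class PipelineStageError(MsitmaError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


class MsitmaWarning(UserWarning):
    """Base class for package warnings (degenerate inputs handled gracefully)."""
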