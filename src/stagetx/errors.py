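"""Exception hierarchy shared across the package."""


class StagetxError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(StagetxError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(StagetxError, ValueError):
    """Runtime data violates an operation's preconditions."""


class FormatError(StagetxError, ValueError):
    """A file could not be parsed as the expected format."""


class PipelineError(StagetxError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
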