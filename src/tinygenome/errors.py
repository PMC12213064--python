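"""Exception hierarchy shared across the package."""


class TinyGenomeError(Exception):
    """Base class for all package errors."""


class ParameterError(TinyGenomeError, ValueError):
    """An argument or configuration value is out of its valid range."""


class FormatError(TinyGenomeError, ValueError):
    """An input file does not conform to the expected format."""


class ConfigurationError(TinyGenomeError, ValueError):
    """A pipeline or role-map configuration is incomplete or inconsistent."""


class StageError(TinyGenomeError, RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
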