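"""Exception hierarchy shared across the pipeline."""


class SviError(Exception):
    """Base class for all package errors."""


class ParameterError(SviError, ValueError):
    """Invalid user-supplied parameter or configuration value."""


class RegistrationError(SviError, RuntimeError):
    """Image registration could not produce a reliable transform."""


class MaskCodecError(SviError, ValueError):
    """Colour-mask encoding or decoding failed."""


class ShapeError(SviError, ValueError):
    """Array shape incompatible with the model or operation."""


class SeriesParseError(SviError, ValueError):
    """A series CSV file failed validation."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StageError(SviError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
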