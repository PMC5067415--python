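"""Exception hierarchy."""


class IdyotError(Exception):
    """Base class for package errors."""


class StreamError(IdyotError):
    """Malformed or inconsistent symbol/event stream."""


class EmptyModelError(IdyotError):
    """A query was made against an untrained model."""


class RegistryError(IdyotError):
    """Chunk registry is missing or corrupt."""


class IdyotIOError(IdyotError):
    """Serialization/deserialization failure; carries a line number when
    the source is a line-oriented file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
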