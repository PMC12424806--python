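"""Exception hierarchy."""


class UnisearchError(Exception):
    """Base class for all package errors."""


class EncodingError(UnisearchError):
    """A sequence could not be 2-bit encoded (ambiguous or illegal base)."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class ParseError(UnisearchError):
    """A file did not conform to the expected dialect."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class IndexFormatError(UnisearchError):
    """A search-index container is corrupt or of an unsupported version."""
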