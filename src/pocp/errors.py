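"""Exception hierarchy shared across the package."""


class PocpError(Exception):
    """Base class for all errors raised by this package."""


class InputError(PocpError):
    """Invalid user input: malformed files, duplicate labels, unknown targets."""


class ParseError(InputError):
    """Malformed line in a tabular or FASTA file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
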