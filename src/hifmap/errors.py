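"""Exception hierarchy shared by all modules."""


class HifmapError(Exception):
    """Base class for all errors raised by hifmap."""


class ValidationError(HifmapError, ValueError):
    """Invalid input data (bad sequence, inconsistent table, unknown code)."""


class ParseError(ValidationError):
    """Malformed input file.

    Carries the 1-based line number of the first offending line when it
    can be determined.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
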