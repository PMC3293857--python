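"""Exception hierarchy for the toolkit.

Every error raised on malformed user input derives from :class:`NfkbKitError`
so CLI entry points can catch one type and exit cleanly.
"""


class NfkbKitError(Exception):
    """Base class for all toolkit errors."""


class MalformedIdentifierError(NfkbKitError):
    """A protein identifier is empty or otherwise unusable; names the token."""


class ParseError(NfkbKitError):
    """A line of an input file could not be parsed.

    Carries the path and 1-based line number for error reporting.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class EmptyInputError(NfkbKitError):
    """An input file or record stream yielded nothing usable."""


class UndefinedMetricError(NfkbKitError):
    """A network statistic is undefined for this graph size."""


class ContingencyError(NfkbKitError):
    """Counts handed to an enrichment test are mutually inconsistent."""


class SyntheticSpecError(NfkbKitError):
    """A synthetic-data specification is infeasible or invalid."""


class StageError(NfkbKitError):
    """A pipeline stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
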