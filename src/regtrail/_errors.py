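"""Exception hierarchy shared across the toolkit.

Input/parse problems and numerical failures are distinguished so that the
command line layer can map them onto distinct exit codes (2 and 3).
"""


class RegTrailError(Exception):
    """Base class for all toolkit errors."""


class InputError(RegTrailError):
    """Invalid or malformed user input (files, parameters, designs)."""


class ParseError(InputError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)


class NumericalError(RegTrailError):
    """A computation failed for numerical reasons (degenerate data, no fit)."""
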