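"""Exception hierarchy shared across the package.

Each error class carries a process exit code so the command-line layer can
map failures to distinct, stable exit statuses: argument errors (2), parse
errors (3), validation errors (4), I/O errors (5).
"""

from __future__ import annotations


class CypnetError(Exception):
    """Base class for all package errors."""

    exit_code: int = 1


class ArgumentError(CypnetError, ValueError):
    """A caller supplied an invalid argument or configuration value."""

    exit_code = 2


class ParseError(CypnetError, ValueError):
    """An input file could not be parsed.

    Where possible the message names the offending line number and token.
    """

    exit_code = 3

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(CypnetError, ValueError):
    """Parsed input violates a semantic constraint (roles, self-loops...)."""

    exit_code = 4


class DegenerateDataError(ValidationError):
    """Data admits no meaningful statistic (e.g. zero variance everywhere)."""

    exit_code = 4
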