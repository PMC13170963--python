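"""Exception hierarchy and CLI exit codes.

Processing failures are kept distinct from a legitimate non-detection:
``NoPeakError`` signals that a trace was processed successfully but no
peak survived the prominence filter, which callers may want to report
rather than treat as a crash.
"""

from __future__ import annotations


class VoltkitError(Exception):
    """Base class for all package errors."""


class ParameterError(VoltkitError, ValueError):
    """A configuration value or function argument is out of contract."""


class InputError(VoltkitError, ValueError):
    """Input data is structurally unusable (empty, too short, missing)."""


class ParseError(InputError):
    """A CSV body cell could not be parsed as a number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(VoltkitError, ValueError):
    """Parsed data violates a domain invariant (e.g. non-finite values)."""


class FitError(VoltkitError, RuntimeError):
    """A baseline fit could not be computed (degenerate abscissa)."""


class NoPeakError(VoltkitError, RuntimeError):
    """No peak was detected; a non-detection, not a processing failure."""


# Stable CLI exit codes (documented in README and tested).
EXIT_OK = 0
EXIT_PARAMETER = 2   # bad flag/config value, threshold missing, ...
EXIT_INPUT = 3       # missing file, empty/short data, parse failure
EXIT_VALIDATION = 4  # non-finite values, invariant violations
EXIT_NO_PEAK = 5     # pipeline ran but detected no peak


def exit_code_for(exc: BaseException) -> int:
    if isinstance(exc, ParameterError):
        return EXIT_PARAMETER
    if isinstance(exc, (ParseError, InputError, FileNotFoundError, OSError)):
        return EXIT_INPUT
    if isinstance(exc, ValidationError):
        return EXIT_VALIDATION
    if isinstance(exc, NoPeakError):
        return EXIT_NO_PEAK
    return 1
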