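"""Exception hierarchy shared by all modules.

Exit-code mapping used by the CLI: validation errors -> 2,
arity/usage errors -> 3, degenerate statistics -> 4.
"""


class PoemError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class InputValidationError(PoemError, ValueError):
    """Malformed or out-of-range input data (bad category, polyline, ...)."""

    exit_code = 2


class DomainError(PoemError, ValueError):
    """An argument outside the mathematical domain of an operation."""

    exit_code = 2


class EmptyClipError(PoemError, ValueError):
    """A clip with no vessel segments was passed to a scoring operation."""

    exit_code = 2

    def __init__(self, clip_id: str):
        self.clip_id = clip_id
        super().__init__(f"empty clip: {clip_id!r} has no vessel segments")


class ArityError(PoemError, ValueError):
    """Wrong number of clips: the overall score requires exactly four."""

    exit_code = 3


class UndefinedValueError(PoemError, ArithmeticError):
    """A ratio whose denominator is empty or zero (PPV, MHI)."""

    exit_code = 4


class DegenerateStatisticsError(PoemError, ArithmeticError):
    """Zero-variance input to a variance-ratio statistic (ICC)."""

    exit_code = 4
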