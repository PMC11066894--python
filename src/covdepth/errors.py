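"""Exception hierarchy shared across the package."""


class CovDepthError(Exception):
    """Base class for fatal, user-facing errors (exit status 1)."""


class FormatError(CovDepthError):
    """Unreadable or malformed input file."""


class ValidationError(CovDepthError):
    """Input violates a documented precondition (bad interval, bad region, ...)."""


class UsageError(CovDepthError):
    """Invalid command-line usage (exit status 2)."""
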