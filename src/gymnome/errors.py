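"""Exception hierarchy for gymnome.

Readers raise :class:`FormatError` with the offending line number rather than
silently skipping malformed rows; numerically undefined results raise typed
errors so callers can distinguish "saturated" from "wrong input".
"""


class GymnomeError(Exception):
    """Base class for all package errors."""


class FormatError(GymnomeError, ValueError):
    """A file violates its declared format contract."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(GymnomeError, ValueError):
    """A value violates a domain invariant."""


class SaturationError(GymnomeError, ArithmeticError):
    """A substitution-distance correction is undefined (log argument <= 0).

    Raised instead of returning NaN so saturated LTR pairs can be counted
    and reported rather than silently propagating.
    """
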