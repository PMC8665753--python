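"""Exception hierarchy.

All library errors derive from :class:`NativeMSError` so callers (and the
CLI) can distinguish domain errors from programming errors.  Input/format
problems map to CLI exit code 1, usage problems to exit code 2.
"""


class NativeMSError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(NativeMSError, ValueError):
    """An operation parameter is out of its documented domain."""


class SpectrumFormatError(NativeMSError, ValueError):
    """A spectrum file violates the two-column CSV contract.

    Carries ``line`` (1-based line number of the offending row) when the
    problem is attributable to a specific line.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SessionSchemaError(NativeMSError, ValueError):
    """A session JSON document is missing required keys or has a wrong version.

    ``missing`` lists the absent field names, if any.
    """

    def __init__(self, message: str, missing: list[str] | None = None):
        self.missing = list(missing or [])
        if self.missing:
            message = f"{message} (missing: {', '.join(self.missing)})"
        super().__init__(message)


class WindowError(NativeMSError, ValueError):
    """A peak-picking window does not overlap the spectrum's m/z range."""

    def __init__(self, message: str, window: tuple[float, float] | None = None):
        self.window = window
        super().__init__(message)


class AssignmentError(NativeMSError, ValueError):
    """Charge-series assignment is impossible for the given peaks."""


class ComplexityError(NativeMSError, ValueError):
    """A combinatorial search would exceed the configured guard."""
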