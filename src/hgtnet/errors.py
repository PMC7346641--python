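"""Exception hierarchy for the hgtnet package.

All errors raised deliberately by the library derive from :class:`HgtNetError`
so callers (and the CLI) can distinguish domain failures from programming
errors.
"""


class HgtNetError(Exception):
    """Base class for all hgtnet errors."""


class FormatError(HgtNetError):
    """A file does not have the expected structure (missing columns, bad header)."""


class ParseError(HgtNetError):
    """A row/field could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(HgtNetError):
    """Parsed data violates a domain invariant."""


class ParameterError(HgtNetError):
    """A function argument is outside its documented domain."""


class InsufficientDataError(HgtNetError):
    """Not enough observations for the requested statistic."""


class DegenerateDataError(HgtNetError):
    """Input has no variation (e.g. all degrees identical) so the fit is undefined."""


class UndefinedMetricError(HgtNetError):
    """The requested metric has no defined value for this input (e.g. empty network)."""


class FitError(HgtNetError):
    """A maximum-likelihood fit failed to converge; carries optimizer diagnostics."""

    def __init__(self, message: str, diagnostics: object = None):
        self.diagnostics = diagnostics
        super().__init__(message)


class TaxonomyLookupError(HgtNetError):
    """A genome accession could not be resolved in the taxonomy table."""


class ConfigError(HgtNetError):
    """Pipeline configuration is invalid (detected before any computation)."""
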