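"""Exception hierarchy shared across the package.

Every user-facing failure raises a :class:`BetascopeError` subclass; the CLI
maps these to exit code 1 and anything else to exit code 2.
"""


class BetascopeError(Exception):
    """Base class for all errors raised by betascope."""


class StoreError(BetascopeError):
    """Problem opening or operating on a store."""


class UnknownBackendError(StoreError):
    """Backend identifier not registered."""


class UnknownProjectError(StoreError):
    """Referenced project has no registered samples."""


class UnknownSampleError(StoreError):
    """Referenced sample is not registered in the project."""


class DuplicateProbeError(StoreError):
    """Probe id appears more than once in an annotation load."""


class DuplicateSampleError(StoreError):
    """Sample id registered twice within a project."""


class BetaRangeError(BetascopeError):
    """A beta value falls outside [0, 1]."""


class AnnotationError(BetascopeError):
    """Invalid annotation record."""


class LocusError(BetascopeError):
    """A locus query string could not be resolved."""


class MetadataError(BetascopeError):
    """Metadata repair could not be applied (e.g. key collision)."""


class ParseError(BetascopeError):
    """Malformed input file.

    Carries optional 1-based ``line`` and ``column`` attributes so callers
    can point at the offending cell.
    """

    def __init__(self, message: str, line: int | None = None, column: str | int | None = None):
        self.line = line
        self.column = column
        loc = ""
        if line is not None:
            loc += f" (line {line}"
            if column is not None:
                loc += f", column {column}"
            loc += ")"
        super().__init__(message + loc)


class GroupSpecError(BetascopeError):
    """Invalid grouping specification."""


class RenderError(BetascopeError):
    """Invalid rendering input or configuration."""


class SimulationError(BetascopeError):
    """Invalid simulation specification."""
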