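"""Exception hierarchy.

Every error raised by the package derives from :class:`PocketEddaError`,
so callers (and the CLI) can distinguish data problems from engine
problems with a single ``except`` clause each.
"""


class PocketEddaError(Exception):
    """Base class for all package errors."""


class FormatError(PocketEddaError):
    """A structure or report file violates its declared format."""


class ParameterError(PocketEddaError):
    """A required per-atom parameter (charge, LJ, Born radius) is missing."""


class GeometryError(PocketEddaError):
    """Atomic geometry is unusable (overlapping atoms, non-finite energy)."""


class CappingError(PocketEddaError):
    """A residue cannot be severed and capped (missing backbone atoms)."""


class EngineError(PocketEddaError):
    """The external energy engine failed or produced unparsable output."""

    def __init__(self, message: str, captured_output: str = ""):
        super().__init__(message)
        self.captured_output = captured_output


class ComparisonError(PocketEddaError):
    """Two binding modes are not comparable (residue fragments differ)."""


class IncompleteBreakdownError(PocketEddaError):
    """A binding-energy breakdown lacks a mandatory term."""


class ArgumentError(PocketEddaError):
    """An operation was called with an invalid argument."""
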