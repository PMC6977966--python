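"""Exception hierarchy.

Exit-code mapping used by the CLI: ValidationError -> 2, ParseError -> 3,
NumericalError -> 4; anything else is an internal error.
"""


class ZipperCapError(Exception):
    """Base class for all package errors."""


class ValidationError(ZipperCapError):
    """Invalid user input: bad spec, bad candidate file, bad parameters."""


class ParseError(ZipperCapError):
    """A structure or table file could not be parsed.

    ``stage`` names the pipeline stage for CLI error reporting.
    """

    def __init__(self, message: str, stage: str = "parse"):
        super().__init__(message)
        self.stage = stage


class EmptyModelError(ParseError):
    """The parsed file contains no protein atoms."""


class AxisDetectionError(ZipperCapError):
    """No consistent inter-strand translation found; supply axis/rise manually."""


class AmbiguousAxisError(AxisDetectionError):
    """Strands are not related by a single consistent translation."""


class InsufficientContextError(ValidationError):
    """Fewer fibril layers available than requested context layers."""


class ThreadingError(ZipperCapError):
    """Candidate cannot be threaded onto the tip template strand."""


class ScoringError(ZipperCapError):
    """A score term could not be computed (e.g. missing backbone atoms)."""


class NumericalError(ZipperCapError):
    """A numerical routine failed to produce a finite result."""
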