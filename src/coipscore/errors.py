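"""Exception hierarchy shared across the package."""


class CoipScoreError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CoipScoreError, ValueError):
    """Malformed or inconsistent input file content."""


class ParameterError(CoipScoreError, ValueError):
    """A parameter outside its documented range."""


class InsufficientDataError(CoipScoreError, ValueError):
    """Too few usable observations for the requested computation."""


class DomainError(CoipScoreError, ValueError):
    """A value outside the mathematical domain of an operation."""
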