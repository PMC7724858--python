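"""Exception hierarchy shared across the pipeline stages."""


class GermnetError(Exception):
    """Base class for all package errors."""


class ArgumentError(GermnetError, ValueError):
    """An argument is outside its documented domain."""


class DataError(GermnetError):
    """Input data is internally inconsistent (counts, coverage, coordinates)."""


class FormatError(GermnetError):
    """A file or table violates its documented format contract."""


class SizingError(GermnetError):
    """A simulation configuration cannot be realised at the requested sizes."""


class InsufficientDataError(GermnetError):
    """Not enough support points / samples for the requested estimate."""
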