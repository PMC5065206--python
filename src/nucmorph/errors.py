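"""Exception types shared across the pipeline."""


class NucmorphError(Exception):
    """Base class for all package errors."""


class NoRegionError(NucmorphError):
    """Raised when an operation that needs a nucleus region finds none."""


class AmbiguousRegionError(NucmorphError):
    """Raised when a mask contains more than one connected component where
    exactly one nucleus is expected."""


class ParameterError(NucmorphError):
    """Invalid parameter value (span, penalty function, alpha, ...)."""


class FormatError(NucmorphError):
    """Input image/CSV does not have the expected layout."""
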