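"""Exception hierarchy shared across the pipeline."""


class AutoregError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AutoregError, ValueError):
    """A configuration value violates its stated invariant."""


class InputError(AutoregError, ValueError):
    """Malformed or incompatible input data (missing channel, bad schema)."""


class InsufficientDataError(AutoregError):
    """Not enough valid data to perform the requested estimate."""


class DegenerateIntersectionError(AutoregError):
    """Two-segment regression produced (near-)parallel lines: no breakpoint."""


class DegenerateVarianceError(AutoregError):
    """A variance required by a statistical test is zero."""
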