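"""Exception types shared across the pipeline."""


class FloatbloomError(Exception):
    """Base class for package errors."""


class InvalidParameterError(FloatbloomError, ValueError):
    """A parameter violates its contract (even window, s outside [0, 1], ...)."""


class UnusableCastError(FloatbloomError, ValueError):
    """A vertical cast cannot support the requested derivation."""


class EmptyClimatologyError(FloatbloomError, ValueError):
    """No populated bins from which to build an annual cycle."""


class IncompleteClimatologyError(FloatbloomError, ValueError):
    """Weekly cycle has empty bins where a complete cycle is required."""

    def __init__(self, empty_bins):
        self.empty_bins = list(empty_bins)
        super().__init__(f"weekly cycle incomplete; empty bins: {self.empty_bins}")
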