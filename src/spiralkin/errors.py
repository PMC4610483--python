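"""Exception types shared across the package."""


class SpiralkinError(Exception):
    """Base class for all package-specific errors."""


class DegenerateTrialError(SpiralkinError):
    """Trial has too few samples for the requested computation."""


class TrialParseError(SpiralkinError):
    """A trial file could not be parsed; message names the offending line."""


class FitError(SpiralkinError):
    """A spiral fit is undefined for the given input."""
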