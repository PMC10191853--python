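"""Exception hierarchy for the flashkin pipeline."""


class FlashkinError(Exception):
    """Base class for all flashkin errors."""


class ValidationError(FlashkinError):
    """A container or parameter violates its invariants."""


class DimensionError(ValidationError):
    """Axes and data arrays disagree in shape."""


class ParseError(FlashkinError):
    """A file could not be parsed; the message names the offending line."""


class ConfigError(FlashkinError):
    """A configuration block is inconsistent or contains unknown keys."""


class DeconvolutionError(FlashkinError):
    """The flash-to-transition weight matrix is unusable (rank/conditioning)."""


class FitError(FlashkinError):
    """A nonlinear fit failed; carries the best parameters found so far."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class StabilityError(FlashkinError):
    """A numerical scheme's stability/validity criterion is violated."""
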