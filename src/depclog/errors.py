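"""Exception hierarchy for depclog."""


class DepclogError(Exception):
    """Base class for all package errors."""


class DomainError(DepclogError, ValueError):
    """A physical argument is outside the model's domain (e.g. f <= 0)."""


class DegenerateInputError(DepclogError, ValueError):
    """Inputs are individually valid but jointly degenerate (e.g. zero
    Clausius-Mossotti denominator, equal outlet haematocrits)."""


class UsageError(DepclogError, ValueError):
    """The caller violated an interface contract (empty grid, unknown flag)."""


class ThresholdOutOfRangeError(DepclogError):
    """A bisection target has no sign change in the searched range."""


class ConfigError(DepclogError, ValueError):
    """Configuration file failed validation; ``errors`` lists all failures."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


class StateError(DepclogError, RuntimeError):
    """An operation was applied to an object in an illegal state."""
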