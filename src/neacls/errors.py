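"""Exception types shared across the package."""


class NeaclsError(Exception):
    """Base class for package errors."""


class InvalidSpecError(NeaclsError, ValueError):
    """A stimulus or model specification violates its constraints."""


class DegenerateBandError(InvalidSpecError):
    """A noise passband contains fewer than two spectrum bins."""


class InvalidConfigError(NeaclsError, ValueError):
    """A configuration object is internally inconsistent."""


class TooFewTrialsError(NeaclsError, ValueError):
    """Not enough trials to fit a loudness profile."""


class UndefinedSlopeError(NeaclsError, ValueError):
    """Loudness-growth slope is undefined (degenerate boundary levels)."""


class InvalidWindowError(NeaclsError, ValueError):
    """The steady-state analysis window is empty."""
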