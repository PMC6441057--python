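"""Exception hierarchy used across the package."""


class SleepCoupleError(Exception):
    """Base class for all package errors."""


class FormatError(SleepCoupleError):
    """Unknown or malformed file format."""


class IntegrityError(SleepCoupleError):
    """Data violates a structural invariant (lengths, ordering, grids)."""


class BoundsError(SleepCoupleError):
    """Requested range lies outside the data."""


class ConfigurationError(SleepCoupleError):
    """Missing channel, invalid parameter, or inconsistent configuration."""


class InputError(SleepCoupleError):
    """Input does not satisfy an operation's preconditions."""
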