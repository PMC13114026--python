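"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class UnitMismatchError(ValidationError):
    """Raised when a threshold is compared against data in a different unit.

    Amplitude criteria are unit-checked: a 5 mV threshold is never silently
    applied to a recording stored in µV.
    """
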