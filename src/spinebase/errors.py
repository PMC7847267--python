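"""Exception types shared across the package."""


class SpinebaseError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpinebaseError, ValueError):
    """A physical or geometric parameter violates its validity domain."""


class AngleDomainError(SpinebaseError, ValueError):
    """Inclination angle outside the model's validity range [0 deg, 90 deg]."""


class TargetOutOfRangeError(SpinebaseError, ValueError):
    """An inverse query asked for a value the model cannot attain on the chosen branch."""


class ParameterFileError(SpinebaseError, ValueError):
    """A parameter file is malformed, has unknown fields, or missing unit suffixes."""
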