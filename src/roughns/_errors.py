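"""Exception hierarchy shared across the package."""


class RoughNSError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(RoughNSError):
    """A user-supplied name, path or option does not match the data."""


class ValidationError(RoughNSError):
    """Input data violates a documented precondition."""


class ShapeMismatchError(RoughNSError):
    """Array dimensions are inconsistent with a fitted state."""
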