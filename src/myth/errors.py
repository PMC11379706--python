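"""Exception hierarchy used across the package."""


class MythError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MythError, ValueError):
    """Invalid input data or arguments."""


class ConfigurationError(MythError, ValueError):
    """Invalid or unknown configuration (backbone names, modes, ...)."""


class FederationError(MythError, RuntimeError):
    """Client/server shape or protocol mismatch during federation."""


class NumericError(MythError, ArithmeticError):
    """Non-finite values encountered where finite numerics are required."""
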