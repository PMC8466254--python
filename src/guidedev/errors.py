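"""Exception types shared across the package."""


class GuidedevError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(GuidedevError):
    """Degenerate geometric input (zero-length implant, non-finite point)."""


class IllPosedRegistrationError(GuidedevError):
    """Point configuration cannot determine a unique rigid transform."""


class ConfigError(GuidedevError):
    """Invalid configuration value or malformed input file."""
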