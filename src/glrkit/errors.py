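"""Exception types shared across glrkit modules."""


class GlrkitError(Exception):
    """Base class for all glrkit errors."""


class ConfigurationError(GlrkitError):
    """Invalid parameter or missing required configuration value."""


class DegenerateScanError(GlrkitError):
    """Line scan unsuitable for background estimation (too few pixels)."""


class CalibrationError(GlrkitError):
    """Threshold calibration inputs are insufficient or invalid."""


class DataIntegrityError(GlrkitError):
    """Input table violates a structural invariant (e.g. decreasing counts)."""


class NonIdentifiableError(GlrkitError):
    """Requested estimate is not identifiable from the given parameters."""
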