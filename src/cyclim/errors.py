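"""Exception hierarchy for the cyclim toolkit."""


class CyclimError(Exception):
    """Base class for all cyclim errors."""


class ConfigError(CyclimError):
    """Invalid configuration, parameters, or stage wiring."""


class InputError(CyclimError):
    """Malformed or inconsistent input data (shapes, ordering, emptiness)."""


class CalibrationError(CyclimError):
    """Unusable calibration data (nonpositive flatfield, singular crosstalk...)."""


class PlacementError(CyclimError):
    """Objects could not be placed in the field without overlap."""


class DegenerateRegistrationError(CyclimError):
    """Registration reference carries no texture to lock onto."""


class BackgroundEstimationError(CyclimError):
    """No usable background pixels to build a background surface from."""


class DegenerateScaleError(CyclimError):
    """The arcsinh normalization has no solution for the given samples."""


class MetadataError(CyclimError):
    """Required image metadata (exposure times, channel ids) is missing."""
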