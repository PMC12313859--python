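"""Exception hierarchy for the stitching pipeline."""


class HsiStitchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HsiStitchError):
    """Invalid configuration value (unknown mode tag, bad threshold, ...)."""


class CalibrationError(HsiStitchError):
    """Calibration bundle unusable (singular matrices, bad distortion model)."""


class SimulationError(HsiStitchError):
    """The synthetic scan cannot be produced (e.g. trajectory leaves scene)."""


class IngestionError(HsiStitchError):
    """Raw stream records missing, duplicated or out of order."""


class EstimationError(HsiStitchError):
    """Homography estimation failed (too few matches, degenerate geometry)."""
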