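"""Exception types shared across the package."""


class SarcotremError(Exception):
    """Base class for package-specific errors."""


class UnscoreableFieldError(SarcotremError):
    """Raised when an image field cannot be scored.

    Typical causes: degenerate intensity (all background or all foreground
    after thresholding), or an empty skeleton.
    """


class CalibrationError(SarcotremError):
    """Raised when spatial calibration (pixel size) is missing or invalid."""


class FitError(SarcotremError):
    """Raised when a model fit fails from every starting point."""
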