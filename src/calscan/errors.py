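"""Exception hierarchy for calscan.

All package errors derive from :class:`CalscanError` so callers can catch
one base class at pipeline boundaries (batch analysis isolates failures
per image by catching it).
"""


class CalscanError(Exception):
    """Base class for all calscan errors."""


class FormatError(CalscanError):
    """An input file could not be read as a supported image format."""


class BoundsError(CalscanError):
    """An ROI or index lies outside the valid extent of its target."""


class ParameterError(CalscanError):
    """A parameter is outside its documented range."""


class InsufficientDataError(CalscanError):
    """Too few samples / peaks / ratios for the requested computation."""


class AmplitudeUndefinedError(CalscanError):
    """Baseline fluorescence is zero or negative, so dF/F0 is undefined.

    Usually signals background-subtracted or miscalibrated input.
    """


class TauUndefinedError(CalscanError):
    """The decay segment cannot support a mono-exponential fit."""


class BatchError(CalscanError):
    """Every image in a batch failed; carries per-image diagnostics."""

    def __init__(self, failures: dict):
        self.failures = failures
        detail = "; ".join(f"{k}: {v}" for k, v in failures.items())
        super().__init__(f"all images in batch failed ({detail})")
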