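"""Exception and warning types shared across the package."""


class FluctraError(Exception):
    """Base class for all package errors."""


class BoxSizeError(FluctraError):
    """Simulation box too small for the PSF or the scan window."""


class DegenerateInputError(FluctraError):
    """Input carries no fluctuations (zero variance), correlation undefined."""


class CalibrationError(FluctraError):
    """PSF or detector calibration produced an implausible result."""


class FormatError(FluctraError):
    """A file on disk does not satisfy the expected layout."""


class EmptyResultError(FluctraError):
    """Every pixel was masked; no statistics can be reported."""


class EmptySelectionError(FluctraError):
    """A selection box captured zero pixels."""


class NormalizationError(FluctraError):
    """Brightness normalization undefined (reference B <= 1)."""


class FluctraWarning(UserWarning):
    """Base class for package warnings."""


class CalibrationWarning(FluctraWarning):
    """Calibration input looks suspect (e.g. drifting dark stack)."""


class ImmobileFeatureWarning(FluctraWarning):
    """ROI overlaps a bright immobile/saturated feature; consider relocating."""


class IllConditionedFitWarning(FluctraWarning):
    """Fit components are nearly degenerate."""


class MultimodalHistogramWarning(FluctraWarning):
    """Brightness histogram has a strong secondary mode."""


class EmptyFieldWarning(FluctraWarning):
    """Simulation rendered with zero particles in the box."""
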