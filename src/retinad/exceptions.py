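"""Exception and warning types shared across the package."""


class RetinadError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RetinadError, ValueError):
    """A simulation or analysis parameter violates its constraints."""


class IncompatibleTracesError(RetinadError, ValueError):
    """Traces differ in length, sampling rate or flash timing."""


class InsufficientBaselineError(RetinadError, ValueError):
    """No usable pre-flash segment from which to estimate the baseline."""


class NyquistError(RetinadError, ValueError):
    """Sampling rate too low for the requested filter band."""


class SegmentationError(RetinadError, RuntimeError):
    """Boundary search failed or produced crossing boundaries."""


class DegenerateGeometryError(RetinadError, ValueError):
    """Phantom boundary curves would cross after undulation/dip."""


class ConfigurationError(RetinadError, ValueError):
    """A cohort design or run configuration is incomplete."""


class CalibrationError(RetinadError, RuntimeError):
    """Waveform amplitude calibration failed to converge."""


class RetinadWarning(UserWarning):
    """Base class for all package warnings."""


class QualityWarning(RetinadWarning):
    """A measured value is suspicious (e.g. non-positive pSTR)."""


class BoundaryPeakWarning(RetinadWarning):
    """A wave extremum landed on the edge of its search window."""


class DegenerateWaveformWarning(RetinadWarning):
    """Input waveform lacks the expected morphology; best-effort values."""


class PartialOpWarning(RetinadWarning):
    """Fewer oscillatory-potential peaks found than requested."""


class LowContrastWarning(RetinadWarning):
    """Image (or a column of it) carries no gradient information."""


class CorrectionBudgetWarning(RetinadWarning):
    """Manual boundary corrections exceed the accepted error budget."""


class PartialSummaryWarning(RetinadWarning):
    """Some B-scans of an eye failed segmentation; mean over the rest."""
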