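"""Exception hierarchy for the staygreen pipeline."""


class StayGreenError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(StayGreenError):
    """Invalid configuration or missing required inputs."""


class CalibrationError(StayGreenError):
    """Empirical-line calibration cannot be fitted (too few / degenerate panels)."""


class ExtractionError(StayGreenError):
    """Plot polygon cannot be extracted from a raster."""


class LayoutError(StayGreenError):
    """Invalid field layout (e.g. overlapping plot polygons)."""


class MissingDataError(StayGreenError):
    """Gap in a daily series that must be contiguous."""

    def __init__(self, message, missing_dates=None):
        super().__init__(message)
        self.missing_dates = list(missing_dates) if missing_dates is not None else []


class InestimableComponentsError(StayGreenError):
    """Design has no replication from which to separate error strata."""


class UndefinedLDError(StayGreenError):
    """LD undefined, typically because a marker is monomorphic."""


class UndefinedCorrelationError(StayGreenError):
    """Correlation undefined because a variable has zero variance."""


class UndefinedReliabilityError(StayGreenError):
    """Reliability denominator is zero (all variance components zero)."""


class EmptyPanelError(StayGreenError):
    """Marker filtering removed every marker."""


class MappingError(StayGreenError):
    """A marker has no entry in the marker map."""


class RankError(StayGreenError):
    """Requested decomposition exceeds the matrix rank."""


class InfeasibleClusteringError(StayGreenError):
    """Fewer cultivars than the minimum haplotype membership."""
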