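"""Exception hierarchy.

Profile-analysis failures are split into distinct classes so that callers can
drop a single sampling line and log the reason code without aborting a whole
artery or run.
"""


class GcxquantError(Exception):
    """Base class for all package errors."""


class SceneError(GcxquantError):
    """Invalid synthetic-scene geometry or parameters."""


class TraceTooShortError(GcxquantError):
    """Wall trace shorter than the requested line layout."""


class ProfileOutOfBoundsError(GcxquantError):
    """A sampling line leaves the image frame."""


class UnknownChannelError(GcxquantError, KeyError):
    """Requested channel not present in the frame."""


class ProfileAnalysisError(GcxquantError):
    """Base class for per-line width-analysis failures."""

    #: short machine-readable reason used in run logs
    reason = "analysis_failed"


class NoPeakError(ProfileAnalysisError):
    """No prominent interior maximum (flat or monotone profile)."""

    reason = "no_peak"


class NoInflectionError(ProfileAnalysisError):
    """Missing second-derivative zero crossing on one side of the peak."""

    reason = "no_inflection"


class NoCrossingError(ProfileAnalysisError):
    """Threshold level never crossed within the profile extent."""

    reason = "no_crossing"


class UnusableArteryError(GcxquantError):
    """Fewer than the required number of usable lines for one artery."""


class RoiPlacementError(GcxquantError):
    """Vessel-free ROI placement infeasible within the attempt budget."""


class StatsError(GcxquantError):
    """Undefined or degenerate statistical computation."""


class ConfigError(GcxquantError):
    """Pipeline configuration failed validation."""
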