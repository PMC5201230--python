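"""Exception hierarchy and machine-readable reason codes.

Delineation failures that correspond to a beat being *unmeasurable* (rather
than a caller contract violation) are not raised: the pipeline returns a
``FiducialSet`` flagged unmeasurable with one of the ``REASON_*`` codes below.
Exceptions are reserved for malformed inputs and configuration errors.
"""


class EcgError(Exception):
    """Base class for all package errors."""


class FormatError(EcgError):
    """Input file or record does not conform to the expected dialect."""


class UnsupportedInputError(EcgError):
    """Input is syntactically valid but outside the supported envelope."""


class ConfigError(EcgError):
    """Invalid configuration value, matrix shape, or unknown method name."""


class NoBeatsError(EcgError):
    """QRS detection found no beats in the record."""


class InsufficientBeatsError(EcgError):
    """Fewer beats than required for baseline removal / median construction."""


class IncompleteMeasurementError(EcgError):
    """A fiducial required for an interval is missing."""


class FeatureError(EcgError):
    """Slur-feature geometry is degenerate (coincident points, no crossing)."""


class TrainingError(EcgError):
    """Relevance-tree training input is unusable (single class, too few)."""


class ClassificationError(EcgError):
    """A feature required by the relevance tree is missing."""


class DegenerateWindowError(EcgError):
    """The T-wave search window is empty (end at or before start)."""


# Reason codes attached to unmeasurable FiducialSets.
REASON_DEGENERATE_WINDOW = "degenerate_window"
REASON_NO_CANDIDATES = "no_candidates"
REASON_NO_PEAK = "no_peak"
REASON_NO_OFFSET = "no_offset"
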