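"""Exception hierarchy.

Every failure mode the pipeline can hit maps to a distinct exception type so
that batch processing can record *why* a trial failed rather than dropping it.
"""


class HDEMGError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HDEMGError):
    """Invalid parameter combination (band edges, durations, amplitudes...)."""


class NoInitiationError(HDEMGError):
    """The force trace never exceeds the initiation threshold."""


class TruncatedWindowError(HDEMGError):
    """The threshold crossing sits too close to the end of the trace for a
    full analysis window."""


class DegenerateMVCError(HDEMGError):
    """An MVC channel is identically zero across all calibration trials,
    which would make %MVC undefined."""


class LayoutMismatchError(HDEMGError):
    """Two objects that must share an electrode layout do not."""


class NormalizationError(HDEMGError):
    """Normalization state is wrong for the requested operation
    (double normalization, or a feature that requires %MVC values)."""


class UndefinedFeatureError(HDEMGError):
    """A spatial feature is mathematically undefined for this map
    (e.g. log or entropy of an all-zero map). Raised, never a sentinel."""


class ParseError(HDEMGError):
    """A file on disk does not match the documented format; the message
    names the offending file and location."""
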