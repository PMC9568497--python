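"""Exception hierarchy for gazecue.

All package-specific failures derive from :class:`GazeCueError` so callers can
catch one base class; subclasses distinguish configuration mistakes, malformed
input tables, sampling problems, and degenerate analyses.
"""


class GazeCueError(Exception):
    """Base class for all gazecue errors."""


class ConfigurationError(GazeCueError):
    """Invalid configuration value (geometry, detector, simulation)."""


class FormatError(GazeCueError):
    """A tabular input file violates the expected schema."""


class SamplingError(GazeCueError):
    """A gaze stream violates the uniform-sampling contract."""


class ValidationError(GazeCueError):
    """A record carries a value outside its allowed domain."""


class DegenerateTrialError(GazeCueError):
    """A per-trial statistic (e.g. the velocity threshold) is undefined."""


class JoinError(GazeCueError):
    """Trial identifiers fail to match across tables."""


class InferenceError(GazeCueError):
    """A resampling analysis cannot produce a defined statistic."""


class DegenerateTableError(GazeCueError):
    """A contingency table has an empty margin, so chi-square is undefined."""
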