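"""Package exception hierarchy."""


class MoodcueError(Exception):
    """Base class for package errors."""


class ConfigurationError(MoodcueError):
    """A study design or run configuration is invalid or infeasible."""


class SchedulingError(MoodcueError):
    """A trial-order constraint could not be satisfied."""


class CalibrationError(MoodcueError):
    """Generator moment-matching failed to converge or targets are infeasible."""
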