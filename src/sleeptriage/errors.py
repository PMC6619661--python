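"""Exception hierarchy for the sleeptriage pipeline."""


class SleepTriageError(Exception):
    """Base class for all package errors."""


class FormatError(SleepTriageError):
    """A file could not be parsed in its declared format."""


class ChannelResolutionError(SleepTriageError):
    """A required channel role (EEG/EOG/EMG) could not be resolved."""


class InsufficientDataError(SleepTriageError):
    """The recording is too short for the requested operation."""


class HypnogramParseError(FormatError):
    """A stage token could not be interpreted; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class CalibrationError(SleepTriageError):
    """Calibration inputs do not cover the required stages."""


class UndefinedValueError(SleepTriageError):
    """The requested statistic is undefined on this input (e.g. empty subset)."""
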