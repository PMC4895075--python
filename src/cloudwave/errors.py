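"""Exception hierarchy shared across the package."""


class CloudwaveError(Exception):
    """Base class for all package-specific errors."""


class EDFFormatError(CloudwaveError):
    """The byte stream violates the EDF layout (bad field, bad width, non-ASCII)."""


class TruncationError(EDFFormatError):
    """The payload ended before the requested records; carries the last complete record."""

    def __init__(self, message: str, last_complete_record: int = -1):
        super().__init__(message)
        self.last_complete_record = last_complete_record


class CalibrationError(CloudwaveError):
    """Degenerate calibration metadata (equal digital or physical extremes)."""


class CorruptionError(CloudwaveError):
    """Sample counts disagree with channel metadata mid-stream."""


class ConfigurationError(CloudwaveError):
    """A configuration value is inconsistent with the recording."""
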