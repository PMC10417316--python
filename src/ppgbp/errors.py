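"""Exception types shared across the pipeline."""


class PPGBPError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PPGBPError, ValueError):
    """An operation received arguments violating its preconditions."""


class EmptySpanError(PPGBPError):
    """A sample span contains no beats to aggregate."""


class LabelExtractionError(PPGBPError):
    """Reference SBP/DBP could not be extracted from an ABP excerpt."""


class StandardizationError(PPGBPError):
    """Z-score standardization failed (zero-variance segment)."""


class TrainingFailureError(PPGBPError):
    """Model training diverged (non-finite loss)."""


class ChannelNotFoundError(PPGBPError, KeyError):
    """A named waveform channel is absent from a record."""


class FormatError(PPGBPError):
    """A record or container file violates the expected layout."""
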