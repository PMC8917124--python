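"""Exception hierarchy for the array-qc pipeline."""


class ArrayQCError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ArrayQCError):
    """Inconsistent or invalid session/pipeline configuration."""


class AlignmentError(ArrayQCError):
    """Event streams cannot be brought into a consistent temporal alignment."""


class ChannelLookupError(ArrayQCError):
    """Out-of-range or unknown channel index."""


class SignalError(ArrayQCError):
    """Invalid signal content (non-finite samples, length mismatch, ...)."""
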