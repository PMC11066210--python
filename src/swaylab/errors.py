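"""Exception hierarchy for swaylab."""


class SwayLabError(Exception):
    """Base class for all swaylab errors."""


class InvalidParameterError(SwayLabError, ValueError):
    """A parameter is outside its documented domain."""


class FormatError(SwayLabError, ValueError):
    """An on-disk artifact does not conform to its documented format."""


class SchemaError(FormatError):
    """A session manifest violates its schema."""


class SegmentationError(SwayLabError, ValueError):
    """A cue interval cannot be mapped onto the recording it refers to."""


class CalibrationError(SwayLabError, RuntimeError):
    """The simulator could not be calibrated to the requested targets."""
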