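"""Exception hierarchy shared across the pipeline."""


class TomopipeError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgument(TomopipeError, ValueError):
    """A precondition on an operation argument was violated."""


class FormatError(TomopipeError, IOError):
    """A file does not follow the expected on-disk layout."""


class DegenerateReference(TomopipeError, ValueError):
    """Flat/dark references cannot normalize the data (e.g. flat == dark)."""


class EstimationFailed(TomopipeError, RuntimeError):
    """A calibration estimate could not be computed reliably."""


class ProtocolError(TomopipeError, RuntimeError):
    """A frame stream violated the message contract."""
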