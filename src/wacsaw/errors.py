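"""Exception hierarchy for the wacsaw package."""


class WacsawError(Exception):
    """Base class for all wacsaw errors."""


class FormatError(WacsawError):
    """A delimited input file does not match the expected layout."""


class SamplingError(WacsawError):
    """The accelerometer record violates the uniform-sampling contract."""


class LogError(WacsawError):
    """An activity log is internally inconsistent (e.g. overlapping intervals)."""


class InputError(WacsawError):
    """An in-memory argument violates an operation's precondition."""


class ValidationError(WacsawError):
    """Prediction and reference series cannot be scored against each other."""
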