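"""Exception hierarchy.

``ShiftCodecError`` is the common base so callers (and the CLI) can map any
package failure to a data/format exit code without enumerating subclasses.
"""


class ShiftCodecError(Exception):
    """Base class for all shiftcodec errors."""


class FormatError(ShiftCodecError):
    """A file could not be parsed in the expected format."""


class SelectorError(ShiftCodecError, LookupError):
    """An entity/assembly selector matched nothing in the file."""


class ParameterError(ShiftCodecError, ValueError):
    """An invalid parameter value was supplied."""


class FittingError(ShiftCodecError):
    """Fitting a filter, scaler or model failed (degenerate or missing data)."""


class CalibrationError(ShiftCodecError):
    """Orientation calibration lacks a required class label."""


class ConfigMismatchError(ShiftCodecError):
    """Components fitted under different atom schemes were combined."""
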