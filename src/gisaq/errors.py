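"""Exception hierarchy for gisaq."""


class GisaqError(Exception):
    """Base class for all gisaq errors."""


class InvalidSequenceError(GisaqError, ValueError):
    """A sequence violates a precondition (empty, bad alphabet, too short)."""


class DesignError(GisaqError):
    """Sequence or primer design failed within the search budget."""


class AssemblyError(GisaqError):
    """A scaffold layout cannot be assembled into a standard."""


class FitError(GisaqError):
    """A regression cannot be fitted (too few points, zero variance)."""


class CalibrationError(GisaqError):
    """Calibration coefficients cannot be computed."""


class QuantificationError(GisaqError):
    """Read counts cannot be converted to absolute abundances."""


class ParseError(GisaqError, ValueError):
    """A file could not be parsed; message names the offending location."""
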