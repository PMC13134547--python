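"""Exception hierarchy for turnkin.

All turnkin errors derive from :class:`TurnkinError` so callers can catch the
package's failures with a single except clause; the finer classes distinguish
bad arguments from data problems (short series, degenerate geometry) and from
analysis outcomes (no turn detected).
"""


class TurnkinError(Exception):
    """Base class for all turnkin errors."""


class InvalidArgumentError(TurnkinError, ValueError):
    """An argument violates a precondition (negative dimension, bad cutoff...)."""


class ShortSeriesError(TurnkinError):
    """The time series is too short for the requested operation."""


class DegenerateGeometryError(TurnkinError):
    """Coincident or collapsed points make a geometric quantity undefined."""


class DegenerateMassError(TurnkinError):
    """Total mass (or a mass-based reference) is zero."""


class DegenerateProfileError(DegenerateMassError):
    """A morphometric profile has zero total volume."""


class NoTurnDetectedError(TurnkinError):
    """The angle series contains no detectable reversal."""


class InsufficientHistoryError(TurnkinError):
    """Not enough frames before the turn start for the pre-turn window."""


class AlignmentError(TurnkinError, ValueError):
    """Two series that must share a time base have different lengths."""


class SchemaError(TurnkinError, ValueError):
    """An input file does not match the documented schema."""
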