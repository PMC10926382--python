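"""Exception hierarchy for vespalocate.

All package-specific failures derive from :class:`VespaLocateError` so that
the CLI can catch one base class and turn it into a diagnostic + nonzero
exit status.
"""


class VespaLocateError(Exception):
    """Base class for all vespalocate errors."""


class ValidationError(VespaLocateError):
    """Invalid input value or empty input where data is required."""


class SchemaError(ValidationError):
    """Input table does not match the expected column schema."""


class OutOfRangeError(ValidationError):
    """Coordinate outside the supported working range of the local frame."""


class DegenerateDirectionError(ValidationError):
    """Bearings cancel out (near-antipodal); no meaningful mean direction."""


class InfeasibleTripError(ValidationError):
    """Round-trip time not longer than the nest-handling time."""


class FrameMismatchError(ValidationError):
    """Geometries from different local frames were combined."""


class DegenerateScenarioError(ValidationError):
    """Simulation scenario is geometrically degenerate (nest on a station)."""
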