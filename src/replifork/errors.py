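"""Exception hierarchy shared across the package."""


class RepliforkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RepliforkError):
    """Invalid or inconsistent user-supplied configuration."""


class GeometryError(RepliforkError):
    """Chromosome geometry that cannot be segmented (e.g. non-positive arcs)."""


class DegenerateDataError(RepliforkError):
    """Input data that leaves nothing to analyse (all bins masked, empty input)."""


class InsufficientDataError(RepliforkError):
    """A stage requires more retained data points than are available."""


class OrientationError(RepliforkError):
    """Marker frequency does not decrease along the expected fork direction."""


class NotApplicableError(RepliforkError):
    """A statistic requested for a strain mode it is not defined for."""


class SimulationError(RepliforkError):
    """Cell-cycle simulation invariant violated (e.g. replication not completing)."""
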