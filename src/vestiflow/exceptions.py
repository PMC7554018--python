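"""Exception hierarchy for vestiflow.

All library errors derive from :class:`VestiflowError` so callers can catch
everything the package raises with a single except clause.
"""


class VestiflowError(Exception):
    """Base class for all vestiflow errors."""


class DegenerateGeometryError(VestiflowError):
    """Geometric input is degenerate (collinear points, zero-length segment...)."""


class TopologyError(VestiflowError):
    """A duct network is disconnected, loop-free, or otherwise ill-posed."""


class RegimeError(VestiflowError):
    """Parameters fall outside the heavily overdamped regime the model assumes."""


class ModelDomainError(VestiflowError):
    """Input is outside the validity domain of a physical formula."""


class ConfigError(VestiflowError):
    """A configuration file violates the labyrinth schema."""
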