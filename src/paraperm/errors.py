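"""Exception hierarchy shared across the toolkit."""


class ParapermError(Exception):
    """Base class for all toolkit errors."""


class ParseError(ParapermError):
    """A file could not be parsed; message names the offending line."""


class FormatError(ParapermError):
    """Unrecognized or unsupported file format."""


class ShapeError(ParapermError):
    """Array/atom-count mismatch between inputs."""


class SelectionError(ParapermError):
    """A selection resolved to no atoms or is otherwise invalid."""


class InsufficientDataError(ParapermError):
    """Not enough frames/samples for the requested statistic."""


class DomainError(ParapermError):
    """Input outside the mathematical domain of an operation."""


class NonPhysicalPotentialError(DomainError):
    """A reversal potential outside the range any permeability ratio can produce."""


class ConfigurationError(ParapermError):
    """Inconsistent or incomplete analysis configuration."""


class StabilityError(ParapermError):
    """Simulation time step too large for the requested conditions."""


class PlacementError(ParapermError):
    """Could not place atoms without overlap in a constructed fixture."""
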