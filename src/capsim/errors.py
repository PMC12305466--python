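"""Exception types shared across the package."""


class CapsimError(Exception):
    """Base class for all capsim errors."""


class InvalidParameterError(CapsimError, ValueError):
    """A scalar parameter is outside its physical domain."""


class InvalidMappingError(CapsimError, ValueError):
    """A unit/parameter bridge is degenerate (e.g. zero slope)."""


class StoichiometryError(CapsimError, ValueError):
    """Component ratios imply non-integer particle counts."""


class CapacityError(CapsimError, ValueError):
    """Simulation box too small for the requested composition."""


class TopologyError(CapsimError, RuntimeError):
    """Bond network inconsistent with the periodic box (unwrapping bug)."""


class InstabilityError(CapsimError, RuntimeError):
    """Integrator produced unphysical displacements; reduce the time step."""


class UndefinedObservableError(CapsimError, ValueError):
    """An observable was requested on an empty or degenerate selection."""
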