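"""Exception hierarchy shared across the package."""


class AttractorTestError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSeriesError(AttractorTestError):
    """A series is constant (or otherwise variance-free) where variance is required."""


class InsufficientDataError(AttractorTestError):
    """A series is too short for the requested embedding or forecast."""


class InvalidBreakpointError(AttractorTestError):
    """A regime breakpoint falls outside the observed time range."""


class SimulationError(AttractorTestError):
    """A simulator produced a non-finite state or failed to integrate."""


class BistabilityError(AttractorTestError):
    """A harvest rate lies outside the bistable window of the skeleton."""
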