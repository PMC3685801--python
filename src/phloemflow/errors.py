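"""Exception hierarchy.

All domain errors derive from :class:`PhloemFlowError` so callers can catch
one type; each subclass also derives from the closest builtin (ValueError or
KeyError) so the functions behave like ordinary Python on bad input.
"""


class PhloemFlowError(Exception):
    """Base class for all package-specific errors."""


class InvalidQuantityError(PhloemFlowError, ValueError):
    """A physical quantity violates its sign/finiteness precondition."""


class InvalidMediumError(PhloemFlowError, ValueError):
    """Transport medium lacks a required property (viscosity, D)."""


class GeometricImpossibilityError(PhloemFlowError, ValueError):
    """Requested geometry cannot be realized (e.g. microchannel wider
    than the cytoplasmic-sleeve circle it must sit on)."""


class NoCrossoverError(PhloemFlowError, ValueError):
    """Diffusion and bulk flow do not cross within the search bracket."""


class NetworkConstructionError(PhloemFlowError, ValueError):
    """Inconsistent manifold-network specification."""


class SingularNetworkError(PhloemFlowError, ValueError):
    """The steady-state system has no unique solution (disconnected)."""


class UnknownFixtureError(PhloemFlowError, KeyError):
    """Requested parameter fixture is not registered."""


class SamplingError(PhloemFlowError, ValueError):
    """Synthetic-bundle sampling ranges are infeasible."""
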