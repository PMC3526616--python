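"""Exception hierarchy shared across the package."""


class AdcascadeError(Exception):
    """Base class for all package-specific errors."""


class MeshParseError(AdcascadeError):
    """A mesh file could not be parsed; the message names the offending line."""


class MeshValidationError(AdcascadeError):
    """A mesh violates the closed-orientable-2-manifold contract."""


class ConnectivityMismatchError(AdcascadeError):
    """Two meshes expected to share atlas connectivity do not."""


class DisconnectedGraphError(AdcascadeError):
    """The k-nearest-neighbour graph is disconnected; message lists component sizes."""


class DegenerateStatisticError(AdcascadeError):
    """A statistic is undefined on the given input (zero variance, constant data...)."""


class CohortError(AdcascadeError):
    """Invalid cohort specification or cohort contents."""
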