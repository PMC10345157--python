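"""Exception hierarchy for the simulation pipeline.

Every stage raises a subclass of :class:`SpindleSimError` so the CLI can
abort with a stage-tagged message.
"""


class SpindleSimError(Exception):
    """Base class for all package errors."""


class InvalidTaskError(SpindleSimError):
    """Unknown end-point task identifier."""


class InvalidResolutionError(SpindleSimError):
    """Requested trajectory resolution is too coarse (< 4 points)."""


class DegeneratePathError(SpindleSimError):
    """A path with zero total arc length cannot be resampled."""


class OutOfWorkspaceError(SpindleSimError):
    """Target end-point position lies outside the reachable annulus."""


class SingularConfigurationError(SpindleSimError):
    """End point coincides with the hip: joint angles are undefined."""


class AnatomicalRangeError(SpindleSimError):
    """Joint angle or musculotendon length outside its admissible range."""


class IntegrationFailureError(SpindleSimError):
    """Intrafusal tension ODE produced a non-finite state."""


class InvalidComponentCountError(SpindleSimError):
    """Requested more principal components than data dimensions."""


class UndefinedCorrelationError(SpindleSimError):
    """Normalized cross-correlation of two constant signals is undefined."""


class IncompleteDesignError(SpindleSimError):
    """Pairwise comparison requested but a study condition is missing."""


class DegenerateTestError(SpindleSimError):
    """Paired test on identical samples (all differences zero)."""
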