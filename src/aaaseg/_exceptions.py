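"""Exception hierarchy for the segmentation pipeline.

Failure modes are named after the pipeline stage that produced them so
that callers (and the CLI exit-code mapping) can distinguish a bad seed
from a degenerate contour or an implausible shape model.
"""


class AAASegError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AAASegError, ValueError):
    """A precondition on user-supplied data was violated."""


class DegenerateContourError(AAASegError):
    """A ray from the centroid failed to intersect the contour.

    Raised when a contour is not star-shaped about the requested ray
    origin, so equiangular landmarking is undefined.
    """


class DegenerateModelError(AAASegError):
    """The training set carries no shape variance (all eigenvalues zero)."""


class LumenFailure(AAASegError):
    """3D level-set lumen segmentation collapsed or missed the lumen."""


class RegistrationFailure(AAASegError):
    """The two channels share no physical overlap containing the lumen."""


class InitFailure(AAASegError):
    """2D level-set thrombus initialization failed on a slice."""


class RegionFailure(AAASegError):
    """No valid boundary candidate in a landmark's search region."""


class SchemaError(AAASegError):
    """A serialized file declares an unsupported schema version or key."""
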