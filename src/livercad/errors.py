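"""Exception types shared across the pipeline.

All errors derive from :class:`LiverCADError` (a ``ValueError``) so callers
can catch pipeline failures with a single except clause while tests can
match on the specific message contracts.
"""


class LiverCADError(ValueError):
    """Base class for all pipeline errors."""


class GridMismatchError(LiverCADError):
    """Phase volumes / mask do not share one voxel grid."""


class EmptyMaskError(LiverCADError):
    """Mask has no foreground voxels."""


class BadPhaseTimesError(LiverCADError):
    """Phase times are not strictly increasing."""


class DegenerateMeshError(LiverCADError):
    """Surface extraction produced no usable closed genus-0 mesh."""


class DuplicateNodeError(LiverCADError):
    """Two mesh nodes coincide on the sphere (zero pairwise distance)."""


class BadAngleError(LiverCADError):
    """Spherical angles outside their principal ranges."""


class InsufficientNodesError(LiverCADError):
    """Fewer mesh nodes than harmonic basis functions."""


class NotNormalizedError(LiverCADError):
    """Co-occurrence matrix does not sum to one."""


class NoCooccurrencesError(LiverCADError):
    """No voxel pair at any admissible offset lies fully inside the mask."""


class EmptyRunMatrixError(LiverCADError):
    """Run-length matrix contains no runs."""


class SchemaError(LiverCADError):
    """Marker records disagree on the marker name schema."""


class UnlabeledSubjectError(LiverCADError):
    """A subject required for supervised training carries no grade."""


class UnknownClassifierError(LiverCADError):
    """Classifier family identifier not recognised."""


class SingleClassError(LiverCADError):
    """Degenerate label vector with a single class."""


class TooManyFoldsError(LiverCADError):
    """More folds requested than subjects available."""


class GridTooSmallError(LiverCADError):
    """Synthetic surface does not fit inside the requested grid."""
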