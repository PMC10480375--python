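"""Exception hierarchy for the augmentation-volumetry pipeline.

Every stage fails loudly with a typed error so that the pipeline driver can
record a structured failure for one scan and continue with the others.
"""


class AugvolError(Exception):
    """Base class for all package errors."""


class MeshIOError(AugvolError):
    """File could not be read or written."""


class EmptyMeshError(AugvolError):
    """A mesh with zero faces where geometry is required."""


class DegenerateLandmarksError(AugvolError):
    """Landmark triple is collinear (no unique rigid alignment)."""


class DegenerateGeometryError(AugvolError):
    """Point set is rank-deficient (e.g. collinear) for pose estimation."""


class InsufficientOverlapError(AugvolError):
    """Fewer than 3 ICP correspondences inside the distance cap."""


class RegistrationQualityError(AugvolError):
    """Post-ICP weighted RMS exceeds the configured quality gate."""


class EmptyCropError(AugvolError):
    """Crop predicate kept no faces."""


class NonManifoldBoundaryError(AugvolError):
    """Boundary edges do not chain into closed cycles."""


class MultiLoopError(AugvolError):
    """Solidification requires exactly one open boundary loop."""


class SolidifyError(AugvolError):
    """Closed solid is self-intersecting or otherwise invalid."""


class InvalidROIError(AugvolError):
    """ROI solid is not watertight or scale factor is out of range."""


class BooleanError(AugvolError):
    """Mesh Boolean operation failed in both exact and voxel engines."""


class OpenMeshError(AugvolError):
    """Enclosed volume requested for a non-watertight mesh."""


class EmptyDiffError(AugvolError):
    """Component filtering called on an empty difference mesh."""


class MarginError(AugvolError):
    """Region of interest extends beyond the scanned surface margin.

    Mirrors the situation where a scan's border lies too close to the
    augmented region for the volume difference to be computed reliably.
    """


class SchemaError(AugvolError):
    """Tabular input is missing required columns or rows."""


class IncompleteDesignError(AugvolError):
    """Reliability analysis requires exactly two ratings per subject."""
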