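"""Exception hierarchy.

Every failure mode documented by the public API raises a named subclass of
:class:`NeckSSMError` so callers (and the pipeline's per-patient error
collection) can distinguish them without string matching.
"""


class NeckSSMError(Exception):
    """Base class for all package errors."""


class MeshFormatError(NeckSSMError):
    """Mesh file exists but could not be parsed in its declared format."""


class EmptyMeshError(NeckSSMError):
    """Mesh parsed but contains no usable geometry."""


class FaceTriangulationError(NeckSSMError):
    """A polygonal face could not be triangulated (fewer than 3 vertices)."""


class InvalidMeshError(NeckSSMError):
    """Mesh violates a container invariant (bad indices, too few vertices)."""


class CenterlineError(NeckSSMError):
    """Centerline violates an invariant (too short, NaN, degenerate)."""


class LandmarkError(NeckSSMError):
    """Landmark coordinates are missing, non-finite, or coincident."""


class LandmarkDistanceError(NeckSSMError):
    """A landmark lies implausibly far from the centerline.

    Usually indicates a unit or coordinate-frame mismatch between inputs.
    """


class RayMissError(NeckSSMError):
    """A cast ray found no wall within the configured maximum radius."""

    def __init__(self, message, station=None, angle_deg=None):
        super().__init__(message)
        self.station = station
        self.angle_deg = angle_deg


class NeckEndNotFoundError(NeckSSMError):
    """Diameter never reached the detection threshold before the CLL end."""

    def __init__(self, message, max_ratio=None):
        super().__init__(message)
        self.max_ratio = max_ratio


class NeckTooShortError(NeckSSMError):
    """Distance between baseline and distal end is below the minimum."""


class ZeroLengthColumnError(NeckSSMError):
    """All ten points of a longitudinal column coincide."""


class DimensionMismatchError(NeckSSMError):
    """Array dimensions in a model/cohort file do not agree."""


class ModelSchemaError(NeckSSMError):
    """Unknown or unsupported model file schema version."""


class SelfIntersectingTubeError(NeckSSMError):
    """Requested tube bends more tightly than its own radius."""


class InfeasibleCohortSpecError(NeckSSMError):
    """Cohort spec rejected: more than half of the draws self-intersect."""


class PatientPipelineError(NeckSSMError):
    """Wrapper adding patient-identifying context to a stage failure."""

    def __init__(self, patient_id, stage, cause):
        super().__init__(f"patient {patient_id!r}: {stage} failed: {cause}")
        self.patient_id = patient_id
        self.stage = stage
        self.cause = cause
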