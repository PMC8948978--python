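"""Core geometric containers: lumen mesh, center lumen line, landmarks.

All coordinates are in millimetres in one shared patient-space frame per
patient. The default axis convention is LPS-like: +x = patient left,
+y = patient posterior, +z = cranial; "anterior" therefore points along -y.
The convention only defines the 0-degree reference direction for contour
rays and the left/right labels of shape modes — no input is ever rescaled
or re-oriented.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import CenterlineError, InvalidMeshError, LandmarkError


def _as_unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


@dataclass(frozen=True)
class AxesConvention:
    """Anatomical axis directions of the shared patient frame."""

    left: tuple = (1.0, 0.0, 0.0)
    posterior: tuple = (0.0, 1.0, 0.0)
    cranial: tuple = (0.0, 0.0, 1.0)

    @property
    def anterior(self) -> np.ndarray:
        return -np.asarray(self.posterior, dtype=float)

    @property
    def left_axis(self) -> np.ndarray:
        return np.asarray(self.left, dtype=float)


#: Default frame: x = left, y = posterior, z = cranial.
LPS = AxesConvention()


def normal_frame(tangent, axes: AxesConvention = LPS, fallback_deg: float = 5.0):
    """In-plane 0-degree reference direction for a cross-section.

    ``ray0`` is patient-anterior projected into the plane normal to
    ``tangent`` and normalized. When the anterior axis lies within
    ``fallback_deg`` of the tangent the projection is ill-conditioned and
    the patient-left axis is used instead.

    Returns
    -------
    ray0 : (3,) unit vector in the normal plane
    """
    t = _as_unit(tangent)
    ref = _as_unit(axes.anterior)
    if abs(float(np.dot(ref, t))) > np.cos(np.deg2rad(fallback_deg)):
        ref = _as_unit(axes.left_axis)
    ray0 = ref - np.dot(ref, t) * t
    return _as_unit(ray0)


@dataclass
class LumenMesh:
    """Triangular surface mesh of the aortic lumen (mm).

    Invariants enforced on construction: at least 4 vertices, all face
    indices valid, every triangle non-degenerate (area > 0).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) < 4:
            raise InvalidMeshError(
                f"mesh needs >= 4 vertices, got {len(self.vertices)}"
            )
        if self.faces.size == 0:
            raise InvalidMeshError("mesh has no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise InvalidMeshError("face indices out of range")
        if not np.isfinite(self.vertices).all():
            raise InvalidMeshError("non-finite vertex coordinates")
        if np.any(self.triangle_areas() <= 0.0):
            raise InvalidMeshError("degenerate (zero-area) triangle present")

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        cr = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class CenterLumenLine:
    """Ordered center-lumen-line polyline with cumulative arc length (mm)."""

    points: np.ndarray
    arc: np.ndarray = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.isfinite(self.points).all():
            raise CenterlineError("non-finite centerline coordinates")
        if len(self.points) < 2:
            raise CenterlineError(
                f"centerline needs >= 2 points, got {len(self.points)}"
            )
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise CenterlineError("duplicate consecutive centerline points")
        self.arc = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc[-1])

    def point_at(self, arc):
        """Point(s) on the polyline at arc position(s), linear interpolation."""
        arc = np.clip(np.asarray(arc, dtype=float), 0.0, self.total_length)
        out = np.stack(
            [np.interp(arc, self.arc, self.points[:, k]) for k in range(3)],
            axis=-1,
        )
        return out

    def tangent_at(self, arc: float, h: float = 0.5) -> np.ndarray:
        """Unit tangent by central difference at arc-length step ``h`` (mm).

        Equivalent to a central difference on the polyline resampled at
        spacing ``h``; one-sided at the ends.
        """
        lo = max(0.0, float(arc) - h)
        hi = min(self.total_length, float(arc) + h)
        if hi <= lo:
            raise CenterlineError("degenerate centerline: zero total length")
        d = self.point_at(hi) - self.point_at(lo)
        return _as_unit(d)

    def resample(self, spacing: float) -> "CenterLumenLine":
        n = max(2, int(np.ceil(self.total_length / spacing)) + 1)
        arcs = np.linspace(0.0, self.total_length, n)
        return CenterLumenLine(self.point_at(arcs))


@dataclass
class NeckLandmarks:
    """LRA orifice coordinate, and optionally the distal neck end (mm)."""

    lra: np.ndarray
    distal_end: np.ndarray | None = None

    def __post_init__(self):
        self.lra = np.asarray(self.lra, dtype=float).reshape(3)
        if not np.isfinite(self.lra).all():
            raise LandmarkError("LRA landmark is non-finite")
        if self.distal_end is not None:
            self.distal_end = np.asarray(self.distal_end, dtype=float).reshape(3)
            if not np.isfinite(self.distal_end).all():
                raise LandmarkError("distal-end landmark is non-finite")
            if np.array_equal(self.distal_end, self.lra):
                raise LandmarkError("distal end coincides with LRA landmark")


def translated(obj, offset):
    """Return a copy of a geometry container translated by ``offset`` (mm)."""
    offset = np.asarray(offset, dtype=float).reshape(3)
    if isinstance(obj, LumenMesh):
        return LumenMesh(obj.vertices + offset, obj.faces.copy())
    if isinstance(obj, CenterLumenLine):
        return CenterLumenLine(obj.points + offset)
    if isinstance(obj, NeckLandmarks):
        de = None if obj.distal_end is None else obj.distal_end + offset
        return NeckLandmarks(obj.lra + offset, de)
    raise TypeError(f"cannot translate {type(obj).__name__}")
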