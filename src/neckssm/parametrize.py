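"""Tubular parametrization of a lumen mesh around its center lumen line.

The neck segment of the CLL — from the projection of the lowest-renal-artery
(LRA) landmark to the distal neck end — is divided into ten equidistant
stations (both endpoints included). At each station 36 rays are cast in the
plane normal to the local CLL tangent, at 10-degree intervals starting from
the patient-anterior reference direction, and intersected with the mesh by
Möller–Trumbore ray–triangle intersection. The result is a 10 x 36 grid of
corresponded contour points (360 per patient).

The distal neck end is taken from the distal landmark when present
(the primary, manually-landmarked mode); otherwise it is detected
automatically as the first arc position where the lumen diameter exceeds
the LRA baseline diameter by 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    LandmarkDistanceError,
    NeckEndNotFoundError,
    NeckTooShortError,
    RayMissError,
)
from .geometry import LPS, AxesConvention, CenterLumenLine, LumenMesh, NeckLandmarks, normal_frame

__all__ = [
    "ParametrizationConfig",
    "StationFrame",
    "ContourGrid",
    "ray_cast",
    "project_point_to_polyline",
    "project_lra",
    "station_frame",
    "measure_diameter",
    "detect_neck_end",
    "place_stations",
    "cast_ring",
    "parametrize",
]


@dataclass(frozen=True)
class ParametrizationConfig:
    """Tunable knobs of the parametrization stage (defaults = study values)."""

    n_stations: int = 10            #: rings along the neck
    n_rays: int = 36                #: rays per ring (10 degree spacing)
    axes: AxesConvention = field(default_factory=lambda: LPS)
    max_lra_distance: float = 30.0  #: mm; beyond this a frame/unit mismatch is assumed
    max_radius: float = 60.0        #: mm; a farther hit means a mesh hole
    min_neck_length: float = 5.0    #: mm; shorter necks are rejected
    detect_step: float = 1.0        #: mm; walk step of the 10%-rule detector
    detect_refine_tol: float = 0.1  #: mm; bisection refinement width
    diameter_ratio: float = 1.10    #: detection threshold vs baseline diameter
    tangent_step: float = 0.5       #: mm; central-difference step for tangents

    def __post_init__(self):
        if self.n_rays < 8:
            raise ValueError("n_rays must be >= 8")
        if self.n_stations < 3:
            raise ValueError("n_stations must be >= 3")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_rays) * (360.0 / self.n_rays)


@dataclass
class StationFrame:
    """Local frame of one station: origin on the CLL, tangent, 0-degree ray."""

    origin: np.ndarray
    tangent: np.ndarray
    ray0: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.tangent = np.asarray(self.tangent, dtype=float).reshape(3)
        self.ray0 = np.asarray(self.ray0, dtype=float).reshape(3)
        for name, v in (("tangent", self.tangent), ("ray0", self.ray0)):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not a unit vector")
        if abs(float(np.dot(self.tangent, self.ray0))) > 1e-9:
            raise ValueError("tangent and ray0 are not orthogonal")

    def ray_directions(self, angles_deg) -> np.ndarray:
        """Unit ray directions at ``angles_deg``, rotating ray0 about the
        tangent (right-handed)."""
        a = np.deg2rad(np.asarray(angles_deg, dtype=float))
        e2 = np.cross(self.tangent, self.ray0)
        return np.cos(a)[:, None] * self.ray0 + np.sin(a)[:, None] * e2


@dataclass
class ContourGrid:
    """Corresponded contour points: ``points[ring, ray] -> (x, y, z)``.

    Rings run proximal (LRA baseline) to distal; rays run 0 to
    360 - 360/n_rays degrees. ``arc_positions`` are the station arc-length
    positions in mm measured from the LRA baseline. ``baseline_point`` is
    the CLL point at the LRA projection (the alignment anchor).
    """

    points: np.ndarray
    arc_positions: np.ndarray
    angles_deg: np.ndarray
    baseline_point: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[2] != 3:
            raise ValueError("points must have shape (rings, rays, 3)")
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite contour points")
        self.arc_positions = np.asarray(self.arc_positions, dtype=float).reshape(-1)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float).reshape(-1)
        if len(self.arc_positions) != self.points.shape[0]:
            raise ValueError("arc_positions length must equal ring count")
        if len(self.angles_deg) != self.points.shape[1]:
            raise ValueError("angles_deg length must equal ray count")
        if self.baseline_point is not None:
            self.baseline_point = np.asarray(self.baseline_point, dtype=float).reshape(3)

    @property
    def n_rings(self) -> int:
        return self.points.shape[0]

    @property
    def n_rays(self) -> int:
        return self.points.shape[1]


# ---------------------------------------------------------------------------
# Ray–triangle intersection (Möller–Trumbore)
# ---------------------------------------------------------------------------

_PARALLEL_EPS = 1e-12   # |det| threshold relative to triangle/ray scale
_BARY_EPS = 1e-9        # inclusive tolerance on barycentric bounds
_T_MIN = 1e-9           # smallest accepted ray parameter (mm)


def ray_cast(origin, directions, mesh: LumenMesh, faces=None):
    """Nearest positive Möller–Trumbore hit of each ray against triangles.

    Parameters
    ----------
    origin : (3,) ray origin shared by all rays
    directions : (k, 3) unit ray directions
    mesh : LumenMesh
    faces : optional (F, 3) triangle subset to test (defaults to all faces)

    Returns
    -------
    dist : (k,) distance to nearest hit, ``inf`` where no hit
    tri : (k,) row index into ``faces`` of the hit triangle, -1 where no hit
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    if faces is None:
        faces = mesh.faces
    if len(faces) == 0:
        k = len(directions)
        return np.full(k, np.inf), np.full(k, -1)
    tv = mesh.vertices[faces]                # (F, 3, 3)
    v0 = tv[:, 0]
    e1 = tv[:, 1] - v0                       # (F, 3)
    e2 = tv[:, 2] - v0

    def dot3(a, b):
        # explicit left-to-right component sum: bitwise-reproducible across
        # vectorized and scalar (per-triangle) evaluation
        return (a[..., 0] * b[..., 0] + a[..., 1] * b[..., 1]) + a[..., 2] * b[..., 2]

    pvec = np.cross(directions[:, None, :], e2[None, :, :])      # (k, F, 3)
    det = dot3(pvec, e1[None, :, :])                             # (k, F)
    scale = np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    ok = np.abs(det) > _PARALLEL_EPS * scale[None, :]
    inv_det = np.where(ok, det, 1.0)

    tvec = origin[None, :] - v0                                  # (F, 3)
    u = dot3(pvec, tvec[None, :, :]) / inv_det
    qvec = np.cross(tvec, e1)                                    # (F, 3)
    v = dot3(directions[:, None, :], qvec[None, :, :]) / inv_det
    t = dot3(e2, qvec)[None, :] / inv_det

    ok &= (u >= -_BARY_EPS) & (v >= -_BARY_EPS) & (u + v <= 1.0 + _BARY_EPS)
    ok &= t > _T_MIN
    t = np.where(ok, t, np.inf)
    tri = np.argmin(t, axis=1)
    dist = t[np.arange(len(directions)), tri]
    tri = np.where(np.isfinite(dist), tri, -1)
    return dist, tri


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def project_point_to_polyline(cll: CenterLumenLine, point) -> tuple[float, float]:
    """Arc position and distance of the closest polyline point to ``point``.

    The point is projected onto every segment (clamped); on ties the more
    proximal (smaller-arc) foot wins.
    """
    p = np.asarray(point, dtype=float).reshape(3)
    a = cll.points[:-1]
    b = cll.points[1:]
    ab = b - a
    seg_len2 = np.einsum("ij,ij->i", ab, ab)
    tpar = np.clip(np.einsum("ij,ij->i", p[None, :] - a, ab) / seg_len2, 0.0, 1.0)
    feet = a + tpar[:, None] * ab
    d2 = np.einsum("ij,ij->i", feet - p, feet - p)
    i = int(np.argmin(d2))  # argmin returns the first (most proximal) minimum
    arc = float(cll.arc[i] + tpar[i] * np.sqrt(seg_len2[i]))
    return arc, float(np.sqrt(d2[i]))


def project_lra(
    cll: CenterLumenLine,
    landmarks: NeckLandmarks,
    max_distance: float = 30.0,
) -> float:
    """Arc position of the LRA landmark's projection onto the CLL (mm)."""
    arc, dist = project_point_to_polyline(cll, landmarks.lra)
    if dist > max_distance:
        raise LandmarkDistanceError(
            f"LRA landmark is {dist:.1f} mm from the CLL "
            f"(max {max_distance:.1f} mm); suspected unit or frame mismatch"
        )
    return arc


def station_frame(
    cll: CenterLumenLine,
    arc: float,
    config: ParametrizationConfig = ParametrizationConfig(),
) -> StationFrame:
    """Local orthonormal frame at an arc position on the CLL."""
    origin = cll.point_at(arc)
    tangent = cll.tangent_at(arc, h=config.tangent_step)
    ray0 = normal_frame(tangent, axes=config.axes)
    return StationFrame(origin, tangent, ray0)


def cast_ring(
    mesh: LumenMesh,
    frame: StationFrame,
    config: ParametrizationConfig = ParametrizationConfig(),
) -> np.ndarray:
    """Contour points of one ring: 36 ray hits in the station's normal plane.

    Raises
    ------
    RayMissError
        if any ray finds no wall, or the nearest hit is farther than
        ``config.max_radius`` (suspected mesh hole).
    """
    dirs = frame.ray_directions(config.angles_deg)
    # all rays lie in the station's normal plane, so only triangles crossing
    # that plane can be hit; pruning the rest is exact (small slack covers
    # the inclusive barycentric tolerance of the intersector)
    zp = (mesh.vertices - frame.origin[None, :]) @ frame.tangent
    zf = zp[mesh.faces]
    cross_plane = (zf.min(axis=1) <= 1e-6) & (zf.max(axis=1) >= -1e-6)
    dist, _ = ray_cast(frame.origin, dirs, mesh, faces=mesh.faces[cross_plane])
    bad = ~np.isfinite(dist) | (dist > config.max_radius)
    if np.any(bad):
        j = int(np.argmax(bad))
        why = "no intersection" if not np.isfinite(dist[j]) else (
            f"hit at {dist[j]:.1f} mm exceeds max radius {config.max_radius:.1f} mm"
        )
        raise RayMissError(
            f"ray at angle {config.angles_deg[j]:.0f} deg from station "
            f"{np.round(frame.origin, 3)}: {why}",
            station=frame.origin.copy(),
            angle_deg=float(config.angles_deg[j]),
        )
    return frame.origin[None, :] + dist[:, None] * dirs


def measure_diameter(
    mesh: LumenMesh,
    frame: StationFrame,
    config: ParametrizationConfig = ParametrizationConfig(),
) -> float:
    """Lumen diameter at a station: twice the mean of the 36 ray lengths.

    The mean-radius definition is rotation-stable and reuses the ray
    machinery; for an ellipse it equals twice the mean polar radius sampled
    at the ray angles.
    """
    pts = cast_ring(mesh, frame, config)
    return float(2.0 * np.mean(np.linalg.norm(pts - frame.origin[None, :], axis=1)))


def detect_neck_end(
    mesh: LumenMesh,
    cll: CenterLumenLine,
    baseline_arc: float,
    config: ParametrizationConfig = ParametrizationConfig(),
) -> float:
    """First arc position where the diameter exceeds baseline by 10%.

    Walks distally from the baseline in ``config.detect_step`` mm steps and
    refines the crossing by bisection to ``config.detect_refine_tol`` mm.
    """
    d0 = measure_diameter(mesh, station_frame(cll, baseline_arc, config), config)
    # tiny relative slack so an exact threshold touch at the CLL end is kept
    thresh = config.diameter_ratio * d0 * (1.0 - 1e-9)

    def diameter(arc: float) -> float:
        return measure_diameter(mesh, station_frame(cll, arc, config), config)

    arcs = np.arange(baseline_arc + config.detect_step, cll.total_length,
                     config.detect_step)
    arcs = np.append(arcs, cll.total_length)
    prev = baseline_arc
    max_ratio = 1.0
    for arc in arcs:
        d = diameter(float(arc))
        max_ratio = max(max_ratio, d / d0)
        if d >= thresh:
            lo, hi = prev, float(arc)
            while hi - lo > config.detect_refine_tol:
                mid = 0.5 * (lo + hi)
                if diameter(mid) >= thresh:
                    hi = mid
                else:
                    lo = mid
            return hi
        prev = float(arc)
    raise NeckEndNotFoundError(
        f"diameter never reached {config.diameter_ratio:.2f} x baseline before "
        f"the CLL end (max ratio found: {max_ratio:.4f})",
        max_ratio=max_ratio,
    )


def place_stations(
    cll: CenterLumenLine,
    baseline_arc: float,
    end_arc: float,
    config: ParametrizationConfig = ParametrizationConfig(),
) -> list[StationFrame]:
    """Equidistant station frames between baseline and distal end.

    ``n_stations`` stations including both endpoints, spaced
    ``(end - baseline) / (n_stations - 1)`` mm apart.
    """
    if end_arc - baseline_arc < config.min_neck_length:
        raise NeckTooShortError(
            f"neck length {end_arc - baseline_arc:.2f} mm is below the "
            f"minimum {config.min_neck_length:.2f} mm"
        )
    arcs = np.linspace(baseline_arc, end_arc, config.n_stations)
    return [station_frame(cll, float(a), config) for a in arcs]


def parametrize(
    mesh: LumenMesh,
    cll: CenterLumenLine,
    landmarks: NeckLandmarks,
    config: ParametrizationConfig = ParametrizationConfig(),
) -> ContourGrid:
    """Full parametrization: landmarks + CLL + mesh -> 10 x 36 contour grid."""
    baseline_arc = project_lra(cll, landmarks, config.max_lra_distance)
    if landmarks.distal_end is not None:
        end_arc, dist = project_point_to_polyline(cll, landmarks.distal_end)
        if dist > config.max_lra_distance:
            raise LandmarkDistanceError(
                f"distal-end landmark is {dist:.1f} mm from the CLL "
                f"(max {config.max_lra_distance:.1f} mm)"
            )
    else:
        end_arc = detect_neck_end(mesh, cll, baseline_arc, config)
    frames = place_stations(cll, baseline_arc, end_arc, config)
    rings = np.stack([cast_ring(mesh, f, config) for f in frames])
    arcs = np.linspace(0.0, end_arc - baseline_arc, config.n_stations)
    return ContourGrid(
        points=rings,
        arc_positions=arcs,
        angles_deg=config.angles_deg,
        baseline_point=cll.point_at(baseline_arc),
    )
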