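"""Synthetic aortic-neck generator with a known low-rank shape model.

Each synthetic patient is a tube around a smooth polynomial centerline from
the LRA baseline at the origin to the distal neck end, with five generative
modes chosen to mirror the anatomical variation an infrarenal-neck shape
model recovers from real cohorts:

* ``length``       — neck length (mm)
* ``bow_lr``       — left/right deflection: apex lateral offset (mm, + = left)
* ``bow_ant``      — anterior deflection: apex anterior offset (mm)
* ``baseline_diameter`` — lumen diameter at the LRA baseline (mm)
* ``distal_tilt``  — angular deflection of the distal neck segment (deg)

plus a fixed conicity (``taper``) and vertex-wise radial Gaussian noise
standing in for segmentation error. Cross-sections are circles perpendicular
to the local centerline tangent; the circumferential vertex layout uses the
same anterior-referenced frame as the parametrization stage, so
:func:`analytic_ring` is an exact closed-form oracle for ray-cast contour
points on noise-free shapes.

Cohort draws are specified in *shape space*: ``CohortSpec.mode_variances``
are the per-contour-point variances (mm^2) each mode contributes to the
processed shape vectors. The generator converts them to parameter standard
deviations through finite-difference sensitivities, and calibrates the
vertex noise so that its share of the total shape variance equals
``noise_variance_fraction`` — both empirically, inside the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .correspond import process_grid
from .errors import InfeasibleCohortSpecError, SelfIntersectingTubeError
from .geometry import LPS, AxesConvention, CenterLumenLine, LumenMesh, NeckLandmarks, normal_frame
from .parametrize import ContourGrid, ParametrizationConfig, parametrize

__all__ = [
    "NeckGenParams",
    "CohortSpec",
    "SyntheticNeck",
    "generate_neck",
    "generate_cohort",
    "analytic_ring",
    "DEFAULT_MODE_VARIANCES",
]

#: names of the five generative modes, in spec order
MODE_NAMES = ("length", "bow_lr", "bow_ant", "baseline_diameter", "distal_tilt")

#: Default shape-space mode variances (mm^2 per contour point), proportional
#: to 51:30:12:2:2 with a total of 9 mm^2 (per-point SD 3 mm) — an
#: anatomically plausible spread for infrarenal necks.
DEFAULT_MODE_VARIANCES = tuple(9.0 * np.array([51.0, 30.0, 12.0, 2.0, 2.0]) / 97.0)

#: normalized station where the distal-tilt deflection begins
_TILT_START = 0.5
#: axial margin (fraction of length) by which the mesh extends past both
#: landmarks, mimicking lumen segmentations that continue beyond the neck
_OVERHANG = 0.04
#: safety factor of the curvature-vs-radius self-intersection check
_CURVATURE_MARGIN = 1.05


@dataclass(frozen=True)
class NeckGenParams:
    """Generative parameters of one synthetic neck."""

    baseline_diameter: float = 24.0   #: mm, lumen diameter at the LRA baseline
    length: float = 30.0              #: mm, LRA baseline to distal neck end
    bow_lr: float = 0.0               #: mm, apex lateral offset (+ = left)
    bow_ant: float = 0.0              #: mm, apex anterior offset
    taper: float = 0.0                #: fractional diameter change per unit t
    distal_tilt: float = 0.0          #: deg, deflection of the distal segment
    noise_sd: float = 0.0             #: mm, vertex-wise radial Gaussian noise
    axial_samples: int = 40           #: mesh rings along the tube
    circumferential_samples: int = 72 #: mesh vertices per ring

    def __post_init__(self):
        if self.baseline_diameter <= 0:
            raise ValueError("baseline_diameter must be > 0")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.axial_samples < 11:
            raise ValueError("axial_samples must be >= 11")
        if self.circumferential_samples < 36:
            raise ValueError("circumferential_samples must be >= 36")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort draw.

    ``mode_variances`` are shape-space variances (mm^2 per contour point)
    for (length, bow_lr, bow_ant, baseline_diameter, distal_tilt).
    """

    n: int = 97
    mode_variances: tuple = DEFAULT_MODE_VARIANCES
    mean_params: NeckGenParams = field(default_factory=NeckGenParams)
    noise_variance_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("cohort needs n >= 3")
        mv = np.asarray(self.mode_variances, dtype=float)
        if mv.shape != (5,) or np.any(mv < 0):
            raise ValueError("mode_variances must be five non-negative values")
        # all-zero variances are allowed: the cohort degenerates to n
        # identical copies of the mean shape (useful for testing)
        if not 0.0 <= self.noise_variance_fraction < 1.0:
            raise ValueError("noise_variance_fraction must be in [0, 1)")


@dataclass
class SyntheticNeck:
    """One generated patient: mesh + centerline + landmarks."""

    mesh: LumenMesh
    cll: CenterLumenLine
    landmarks: NeckLandmarks


# ---------------------------------------------------------------------------
# Closed-form tube geometry
# ---------------------------------------------------------------------------

def _centerline_point(params: NeckGenParams, t, axes: AxesConvention = LPS):
    """Centerline c(t) for normalized station t (vectorized).

    Lateral deflections use the bump 4 t (1 - t) (zero, with zero slope in
    the deflection direction, at both ends); the distal tilt adds a smooth
    quadratic ramp beyond t = 0.5 whose end slope equals tan(tilt).
    """
    t = np.asarray(t, dtype=float)
    L = params.length
    bump = 4.0 * t * (1.0 - t)
    tilt = np.tan(np.deg2rad(params.distal_tilt))
    ramp = np.where(
        t > _TILT_START,
        ((t - _TILT_START) / (1.0 - _TILT_START)) ** 2,
        0.0,
    )
    x = params.bow_lr * bump + tilt * L * (1.0 - _TILT_START) / 2.0 * ramp
    y = -params.bow_ant * bump          # anterior = -y in the LPS-like frame
    z = t * L
    return (
        x[..., None] * axes.left_axis
        + y[..., None] * np.asarray(axes.posterior, dtype=float)
        + z[..., None] * np.asarray(axes.cranial, dtype=float)
    )


def _centerline_tangent(params: NeckGenParams, t, axes: AxesConvention = LPS):
    """Analytic unit tangent dc/dt normalized (vectorized)."""
    t = np.asarray(t, dtype=float)
    L = params.length
    dbump = 4.0 - 8.0 * t
    tilt = np.tan(np.deg2rad(params.distal_tilt))
    dramp = np.where(
        t > _TILT_START,
        2.0 * (t - _TILT_START) / (1.0 - _TILT_START) ** 2,
        0.0,
    )
    dx = params.bow_lr * dbump + tilt * L * (1.0 - _TILT_START) / 2.0 * dramp
    dy = -params.bow_ant * dbump
    dz = np.full_like(t, L)
    d = (
        dx[..., None] * axes.left_axis
        + dy[..., None] * np.asarray(axes.posterior, dtype=float)
        + dz[..., None] * np.asarray(axes.cranial, dtype=float)
    )
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def _radius(params: NeckGenParams, t):
    return 0.5 * params.baseline_diameter * (1.0 + params.taper * np.asarray(t, dtype=float))


def _ring_points(params: NeckGenParams, t: float, angles_deg, axes: AxesConvention = LPS):
    """Exact circle points at station t for the given angles (degrees)."""
    c = _centerline_point(params, t, axes)
    tan = _centerline_tangent(params, t, axes)
    ray0 = normal_frame(tan, axes)
    e2 = np.cross(tan, ray0)
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    r = _radius(params, t)
    return c[None, :] + r * (np.cos(a)[:, None] * ray0 + np.sin(a)[:, None] * e2)


def analytic_ring(
    params: NeckGenParams,
    t: float,
    angle_deg,
    axes: AxesConvention = LPS,
) -> np.ndarray:
    """Exact surface point(s) at normalized station ``t`` and angle(s).

    Closed-form oracle for ray-cast contour points; only defined for
    noise-free shapes.
    """
    if params.noise_sd > 0:
        raise ValueError("analytic_ring requires noise_sd = 0")
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must be in [0, 1]")
    pts = _ring_points(params, float(t), np.atleast_1d(angle_deg), axes)
    return pts[0] if np.isscalar(angle_deg) else pts


def _check_self_intersection(params: NeckGenParams, axes: AxesConvention = LPS) -> None:
    """Reject tubes whose centerline bends more tightly than the tube radius.

    Heuristic: adjacent cross-section planes must not intersect within the
    tube; equivalently the local curvature radius (estimated from dense
    tangent samples) must exceed the local tube radius with a small margin.
    """
    ts = np.linspace(0.0, 1.0, 201)
    pts = _centerline_point(params, ts, axes)
    tans = _centerline_tangent(params, ts, axes)
    ds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    dots = np.clip(np.einsum("ij,ij->i", tans[:-1], tans[1:]), -1.0, 1.0)
    dtheta = np.arccos(dots)
    with np.errstate(divide="ignore"):
        curv_radius = np.where(dtheta > 0, ds / dtheta, np.inf)
    r_local = _radius(params, 0.5 * (ts[:-1] + ts[1:]))
    if np.any(r_local <= 0):
        raise SelfIntersectingTubeError("tube radius becomes non-positive")
    if np.any(curv_radius < _CURVATURE_MARGIN * r_local):
        worst = float(np.min(curv_radius / r_local))
        raise SelfIntersectingTubeError(
            f"centerline curvature radius falls to {worst:.2f} x tube radius; "
            "bow/tilt too large relative to diameter and length"
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_neck(params: NeckGenParams, seed: int, axes: AxesConvention = LPS):
    """One synthetic neck: (LumenMesh, CenterLumenLine, NeckLandmarks).

    Deterministic given ``seed``. The mesh is a tube of circular
    cross-sections (plus radial vertex noise), closed circumferentially and
    capped at both ends with rim fans, extending a small axial margin past
    the landmarks. The centerline and landmarks span exactly t in [0, 1].
    """
    _check_self_intersection(params, axes)
    rng = np.random.default_rng(seed)
    A, C = params.axial_samples, params.circumferential_samples
    ts = np.linspace(-_OVERHANG, 1.0 + _OVERHANG, A)
    angles = np.arange(C) * (360.0 / C)

    verts = np.empty((A, C, 3))
    for i, t in enumerate(ts):
        verts[i] = _ring_points(params, float(t), angles, axes)
    if params.noise_sd > 0:
        centers = _centerline_point(params, ts, axes)
        radial = verts - centers[:, None, :]
        radial /= np.linalg.norm(radial, axis=2, keepdims=True)
        verts = verts + rng.normal(0.0, params.noise_sd, (A, C))[..., None] * radial

    faces = []
    for i in range(A - 1):
        for j in range(C):
            jn = (j + 1) % C
            a, b = i * C + j, i * C + jn
            c, d = (i + 1) * C + jn, (i + 1) * C + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    # rim-fan caps (no extra vertices): keeps the tube watertight while all
    # vertices stay on the lateral surface
    for j in range(1, C - 1):
        faces.append((0, j + 1, j))                              # proximal
        base = (A - 1) * C
        faces.append((base, base + j, base + j + 1))             # distal
    mesh = LumenMesh(verts.reshape(-1, 3), np.asarray(faces, dtype=np.int64))

    cll_t = np.linspace(0.0, 1.0, 101)
    cll = CenterLumenLine(_centerline_point(params, cll_t, axes))
    landmarks = NeckLandmarks(
        lra=_centerline_point(params, 0.0, axes),
        distal_end=_centerline_point(params, 1.0, axes),
    )
    return mesh, cll, landmarks


# ---------------------------------------------------------------------------
# Cohort draws with empirical shape-space calibration
# ---------------------------------------------------------------------------

_CANON_T = np.linspace(0.0, 1.0, 10)


def _shape_functional(params: NeckGenParams, config: ParametrizationConfig,
                      axes: AxesConvention = LPS) -> np.ndarray:
    """Processed shape vector of the noise-free analytic surface: the exact
    contour grid at the canonical stations, rearranged and aligned."""
    ts = np.linspace(0.0, 1.0, config.n_stations)
    pts = np.stack([_ring_points(params, float(t), config.angles_deg, axes) for t in ts])
    grid = ContourGrid(pts, ts * params.length, config.angles_deg,
                       baseline_point=_centerline_point(params, 0.0, axes))
    return process_grid(grid)


def _mode_sensitivities(mean: NeckGenParams, config: ParametrizationConfig,
                        axes: AxesConvention = LPS) -> np.ndarray:
    """Per-point RMS shape displacement per unit change of each mode
    parameter, by central finite differences of the analytic shape vector."""
    deltas = dict(length=1.0, bow_lr=1.0, bow_ant=1.0,
                  baseline_diameter=1.0, distal_tilt=1.0)
    n_pts = config.n_stations * config.n_rays
    g = np.empty(5)
    for i, name in enumerate(MODE_NAMES):
        d = deltas[name]
        hi = _shape_functional(replace(mean, **{name: getattr(mean, name) + d}), config, axes)
        lo = _shape_functional(replace(mean, **{name: getattr(mean, name) - d}), config, axes)
        g[i] = np.linalg.norm(hi - lo) / (2.0 * d) / np.sqrt(n_pts)
    return g


def _noise_unit_variance(mean: NeckGenParams, config: ParametrizationConfig,
                         rng: np.random.Generator, n_probe: int = 4,
                         axes: AxesConvention = LPS) -> float:
    """Per-contour-point variance (mm^2, 3D) induced in processed shape
    vectors by unit vertex noise, measured by parametrizing probe meshes."""
    clean = replace(mean, noise_sd=0.0)
    m0, cll0, lm0 = generate_neck(clean, seed=0, axes=axes)
    v0 = process_grid(parametrize(m0, cll0, lm0, config))
    n_pts = config.n_stations * config.n_rays
    acc = 0.0
    for _ in range(n_probe):
        seed = int(rng.integers(2**31))
        m, cll, lm = generate_neck(replace(mean, noise_sd=1.0), seed=seed, axes=axes)
        v = process_grid(parametrize(m, cll, lm, config))
        acc += float(np.sum((v - v0) ** 2)) / n_pts
    return acc / n_probe


def generate_cohort(
    spec: CohortSpec,
    config: ParametrizationConfig | None = None,
    axes: AxesConvention = LPS,
):
    """Draw a synthetic cohort.

    Returns
    -------
    necks : list of SyntheticNeck
    truth : dict with the true per-shape draws and calibration constants:
        ``mode_scores`` (n, 5) shape-space draws (mm per point),
        ``mode_offsets`` (n, 5) parameter-space offsets,
        ``param_sds``, ``sensitivities``, ``noise_sd``.

    Raises
    ------
    InfeasibleCohortSpecError
        if more than half of the attempted draws self-intersect.
    """
    if config is None:
        config = ParametrizationConfig()
    rng = np.random.default_rng(spec.seed)
    mv = np.asarray(spec.mode_variances, dtype=float)

    g = _mode_sensitivities(spec.mean_params, config, axes)
    param_sds = np.where(g > 0, np.sqrt(mv) / np.where(g > 0, g, 1.0), 0.0)

    f = spec.noise_variance_fraction
    if f > 0:
        target_noise_var = mv.sum() * f / (1.0 - f)
        unit_var = _noise_unit_variance(spec.mean_params, config, rng, axes=axes)
        noise_sd = float(np.sqrt(target_noise_var / unit_var))
    else:
        noise_sd = 0.0

    necks: list[SyntheticNeck] = []
    mode_scores = np.empty((spec.n, 5))
    mode_offsets = np.empty((spec.n, 5))
    rejections = 0
    i = 0
    while i < spec.n:
        if rejections > max(spec.n, 2 * (i + 1)):
            raise InfeasibleCohortSpecError(
                f"{rejections} self-intersection rejections while drawing "
                f"{i} shapes; spec infeasible"
            )
        z = rng.standard_normal(5) * np.sqrt(mv)
        offsets = np.where(param_sds > 0, z / np.where(g > 0, g, 1.0), 0.0)
        kwargs = {name: getattr(spec.mean_params, name) + offsets[j]
                  for j, name in enumerate(MODE_NAMES)}
        seed = int(rng.integers(2**31))
        try:
            params = replace(spec.mean_params, noise_sd=noise_sd, **kwargs)
            mesh, cll, lm = generate_neck(params, seed=seed, axes=axes)
        except (SelfIntersectingTubeError, ValueError):
            rejections += 1
            continue
        necks.append(SyntheticNeck(mesh, cll, lm))
        mode_scores[i] = z
        mode_offsets[i] = offsets
        i += 1

    truth = {
        "mode_names": list(MODE_NAMES),
        "mode_scores": mode_scores,
        "mode_offsets": mode_offsets,
        "param_sds": param_sds,
        "sensitivities": g,
        "noise_sd": noise_sd,
        "rejections": rejections,
    }
    return necks, truth
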