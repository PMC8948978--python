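"""Readers and writers for the per-patient inputs and fitted artifacts.

Meshes (STL/PLY/OBJ) go through :mod:`trimesh`; centerlines and landmarks
are plain CSV/JSON; models and evaluation reports use a self-describing,
versioned JSON container. Units are millimetres everywhere and no reader
rescales or reorders anything.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .correspond import ShapeCohort
from .errors import (
    DimensionMismatchError,
    EmptyMeshError,
    FaceTriangulationError,
    MeshFormatError,
    ModelSchemaError,
)
from .evaluate import EvalReport
from .geometry import CenterLumenLine, LumenMesh, NeckLandmarks
from .parametrize import ContourGrid
from .ssm import SSMModel

MODEL_SCHEMA_VERSION = 1
_MESH_SUFFIXES = {".stl", ".ply", ".obj"}


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def read_mesh(path) -> LumenMesh:
    """Load an STL/PLY/OBJ surface mesh (mm).

    Polygonal faces are triangulated deterministically by fanning from the
    first vertex (a quad is split along its first diagonal).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix not in _MESH_SUFFIXES:
        raise MeshFormatError(f"unsupported mesh format {suffix!r} ({path})")
    try:
        tm = trimesh.load_mesh(path, file_type=suffix[1:], process=False)
    except ValueError as exc:
        if "triangulate" in str(exc).lower():
            raise FaceTriangulationError(f"{path}: {exc}") from exc
        raise MeshFormatError(f"cannot parse {path}: {exc}") from exc
    except Exception as exc:  # trimesh raises various loader errors
        raise MeshFormatError(f"cannot parse {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"no geometry in {path}")
        tm = trimesh.util.concatenate(geoms)
    vertices = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if vertices.size == 0 or faces.size == 0:
        raise EmptyMeshError(f"no usable geometry in {path}")
    if faces.shape[1] != 3:
        raise FaceTriangulationError(f"{path}: non-triangular faces survived loading")
    # drop zero-area triangles (duplicated vertices in sloppy exports)
    v = vertices[faces]
    areas = 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)
    if np.any(areas <= 0):
        warnings.warn(f"{path}: dropping {int((areas <= 0).sum())} degenerate triangle(s)")
        faces = faces[areas > 0]
        if faces.size == 0:
            raise EmptyMeshError(f"only degenerate triangles in {path}")
    return LumenMesh(vertices, faces)


def write_mesh(mesh: LumenMesh, path) -> None:
    """Write a mesh as STL/PLY/OBJ (ASCII where the format supports it)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _MESH_SUFFIXES:
        raise MeshFormatError(f"unsupported mesh format {suffix!r} ({path})")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    kwargs = {"encoding": "ascii"} if suffix == ".ply" else {}
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=suffix[1:], **kwargs)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# Centerlines and landmarks
# ---------------------------------------------------------------------------

def read_centerline(path) -> CenterLumenLine:
    """Load an ordered CLL polyline from CSV (x,y,z; header optional) or JSON.

    Duplicate consecutive points are collapsed with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        pts = np.asarray(json.loads(path.read_text()), dtype=float)
    else:
        first = path.read_text().lstrip().splitlines()[0] if path.stat().st_size else ""
        has_header = any(not _is_number(tok) for tok in first.split(",") if tok.strip())
        df = pd.read_csv(path, header=0 if has_header else None, comment="#")
        pts = df.to_numpy(dtype=float)
    pts = np.atleast_2d(pts)
    from .errors import CenterlineError

    if pts.shape[-1] != 3:
        raise CenterlineError(f"{path}: expected 3 columns, got {pts.shape[-1]}")
    if not np.isfinite(pts).all():
        raise CenterlineError(f"{path}: non-finite centerline coordinates")
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    if not keep.all():
        warnings.warn(f"{path}: collapsed {int((~keep).sum())} duplicate consecutive point(s)")
        pts = pts[keep]
    return CenterLumenLine(pts)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_centerline(cll: CenterLumenLine, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cll.points.tolist()))
    else:
        pd.DataFrame(cll.points, columns=["x", "y", "z"]).to_csv(path, index=False)


def read_landmarks(path) -> NeckLandmarks:
    """Load landmarks from JSON ({"lra": [...], "distal_end": [...] | null})
    or CSV (rows: name,x,y,z)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return NeckLandmarks(data["lra"], data.get("distal_end"))
    df = pd.read_csv(path, header=None, names=["name", "x", "y", "z"], comment="#")
    rows = {str(r["name"]).strip().lower(): [r.x, r.y, r.z] for _, r in df.iterrows()}
    return NeckLandmarks(rows["lra"], rows.get("distal_end"))


def write_landmarks(landmarks: NeckLandmarks, path) -> None:
    path = Path(path)
    de = None if landmarks.distal_end is None else landmarks.distal_end.tolist()
    path.write_text(json.dumps({"lra": landmarks.lra.tolist(), "distal_end": de}))


# ---------------------------------------------------------------------------
# Contour grids
# ---------------------------------------------------------------------------

def write_grid(grid: ContourGrid, path) -> None:
    """Contour grid as CSV: one row per contour point."""
    rows = []
    for i in range(grid.n_rings):
        for j in range(grid.n_rays):
            rows.append(
                (i, j, grid.angles_deg[j], *grid.points[i, j], grid.arc_positions[i])
            )
    df = pd.DataFrame(rows, columns=["ring", "ray", "angle_deg", "x", "y", "z", "arc_mm"])
    df.to_csv(path, index=False)


def read_grid(path) -> ContourGrid:
    df = pd.read_csv(path, comment="#")
    n_rings = int(df["ring"].max()) + 1
    n_rays = int(df["ray"].max()) + 1
    if len(df) != n_rings * n_rays:
        raise DimensionMismatchError(f"{path}: incomplete grid ({len(df)} rows)")
    df = df.sort_values(["ring", "ray"])
    pts = df[["x", "y", "z"]].to_numpy().reshape(n_rings, n_rays, 3)
    arcs = df.groupby("ring")["arc_mm"].first().to_numpy()
    angles = df[df["ring"] == 0]["angle_deg"].to_numpy()
    return ContourGrid(pts, arcs, angles)


# ---------------------------------------------------------------------------
# Cohort matrices
# ---------------------------------------------------------------------------

def write_cohort(cohort: ShapeCohort, path) -> None:
    df = pd.DataFrame(cohort.matrix, index=cohort.ids, columns=cohort.column_labels())
    df.index.name = "id"
    df.to_csv(path)


def read_cohort(path, n_rings: int = 10, n_rays: int = 36) -> ShapeCohort:
    df = pd.read_csv(path, index_col=0, comment="#")
    return ShapeCohort(list(df.index), df.to_numpy(dtype=float), n_rings, n_rays)


# ---------------------------------------------------------------------------
# Models and reports
# ---------------------------------------------------------------------------

def write_model(model: SSMModel, path) -> None:
    """Serialize a fitted model losslessly to a versioned JSON container."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "n_rings": model.n_rings,
        "n_rays": model.n_rays,
        "n_train": model.n_train,
        "ids": model.ids,
        "mean": model.mean.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "eigenvectors": model.eigenvectors.tolist(),
        "scores": model.scores.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> SSMModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = json.loads(path.read_text())
    version = data.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelSchemaError(f"{path}: unknown model schema version {version!r}")
    mean = np.asarray(data["mean"], dtype=float)
    vecs = np.asarray(data["eigenvectors"], dtype=float)
    vals = np.asarray(data["eigenvalues"], dtype=float)
    scores = np.asarray(data["scores"], dtype=float)
    if vecs.size and (vecs.ndim != 2 or vecs.shape[0] != mean.size):
        raise DimensionMismatchError(
            f"{path}: eigenvector matrix {vecs.shape} does not match "
            f"mean length {mean.size}"
        )
    if vecs.size == 0:
        vecs = vecs.reshape(mean.size, 0)
        scores = scores.reshape(int(data["n_train"]), 0)
    if vecs.shape[1] != vals.size:
        raise DimensionMismatchError(f"{path}: eigenvalue/eigenvector count mismatch")
    return SSMModel(
        mean=mean,
        eigenvectors=vecs,
        eigenvalues=vals,
        scores=scores,
        n_train=int(data["n_train"]),
        n_rings=int(data["n_rings"]),
        n_rays=int(data["n_rays"]),
        ids=list(data.get("ids", [])),
    )


def write_report(report: EvalReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def report_to_csv(report: EvalReport, path) -> None:
    rows = [("compactness", i + 1, c, "", "")
            for i, c in enumerate(report.compactness)]
    for name, section in (("generalization", report.generalization),
                          ("specificity", report.specificity)):
        for k in sorted(section):
            s = section[k]
            rows.append((name, k, s.mean, s.ci_low, s.ci_high))
    pd.DataFrame(rows, columns=["metric", "k", "value", "ci95_low", "ci95_high"]).to_csv(
        path, index=False
    )


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
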