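"""End-to-end orchestration: ingest/generate -> parametrize -> align -> fit
-> evaluate -> export, with structured logging and reproducibility controls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as nio
from .correspond import ShapeCohort, cohort_from_grids
from .errors import NeckSSMError, PatientPipelineError
from .evaluate import evaluate_all
from .parametrize import ParametrizationConfig, parametrize
from .ssm import fit_ssm, mode_mesh
from .synthetic import CohortSpec, SyntheticNeck, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "cohort_matrix_from_necks", "load_patient_dir"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full-pipeline configuration (defaults are the study values)."""

    input_dir: str | None = None          #: directory of per-patient subdirs
    synthetic: CohortSpec | None = None   #: or generate the cohort instead
    n_stations: int = 10
    n_rays: int = 36
    neck_end_mode: str = "landmark"       #: "landmark" | "10pct-rule"
    k_values: tuple = (5, 9)
    specificity_samples: int = 1000
    seed: int = 0
    mode_sd: tuple = (-3.0, 3.0)          #: SD multipliers for mode meshes
    n_mode_meshes: int = 5
    skip_failures: bool = False

    def __post_init__(self):
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir / synthetic must be set")
        if self.neck_end_mode not in ("landmark", "10pct-rule"):
            raise ValueError(f"unknown neck_end_mode {self.neck_end_mode!r}")

    def parametrization(self) -> ParametrizationConfig:
        return ParametrizationConfig(n_stations=self.n_stations, n_rays=self.n_rays)

    def hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_patient_dir(patient_dir: Path) -> SyntheticNeck:
    """Read one patient subdirectory (mesh.* / cll.* / landmarks.*)."""
    patient_dir = Path(patient_dir)

    def pick(stem, exts):
        for ext in exts:
            p = patient_dir / f"{stem}{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(f"no {stem} file in {patient_dir}")

    mesh = nio.read_mesh(pick("mesh", (".ply", ".stl", ".obj")))
    cll = nio.read_centerline(pick("cll", (".csv", ".json")))
    lm = nio.read_landmarks(pick("landmarks", (".json", ".csv")))
    return SyntheticNeck(mesh, cll, lm)


def cohort_matrix_from_necks(necks, ids=None, config=None,
                             neck_end_mode: str = "landmark") -> ShapeCohort:
    """Parametrize, rearrange, align and stack a list of necks."""
    if config is None:
        config = ParametrizationConfig()
    grids = []
    for neck in necks:
        lm = neck.landmarks
        if neck_end_mode == "10pct-rule":
            lm = dataclasses.replace(lm, distal_end=None)
        grids.append(parametrize(neck.mesh, neck.cll, lm, config))
    return cohort_from_grids(grids, ids)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``). Raises
    :class:`PatientPipelineError` on the first per-patient failure unless
    ``config.skip_failures`` is set, in which case failed patients are
    logged and excluded.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "grids").mkdir(exist_ok=True)
    (out / "modes").mkdir(exist_ok=True)
    cfg_hash = config.hash()
    log_path = out / "log.jsonl"
    t0 = time.perf_counter()

    def log(event: str, **kw):
        rec = {"t": round(time.perf_counter() - t0, 3), "event": event,
               "config_hash": cfg_hash, **_jsonable(kw)}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(rec) + "\n")

    log_path.write_text("")
    log("start", config=_jsonable(dataclasses.asdict(config)))
    pconfig = config.parametrization()

    failed: list[str] = []
    if config.synthetic is not None:
        necks, truth = generate_cohort(config.synthetic, pconfig)
        ids = [f"S{i:03d}" for i in range(len(necks))]
        (out / "truth.json").write_text(json.dumps(_jsonable(truth)))
        log("synthesized", n=len(necks), noise_sd=truth["noise_sd"])
    else:
        root = Path(config.input_dir)
        dirs = sorted(p for p in root.iterdir() if p.is_dir())
        necks, ids = [], []
        for p in dirs:
            try:
                necks.append(load_patient_dir(p))
                ids.append(p.name)
            except (NeckSSMError, OSError, KeyError) as exc:
                log("patient_failed", patient=p.name, stage="load", error=str(exc))
                if not config.skip_failures:
                    raise PatientPipelineError(p.name, "load", exc) from exc
                failed.append(p.name)
        log("loaded", n=len(necks))

    grids, kept_ids = [], []
    for pid, neck in zip(ids, necks):
        lm = neck.landmarks
        if config.neck_end_mode == "10pct-rule":
            lm = dataclasses.replace(lm, distal_end=None)
        try:
            grid = parametrize(neck.mesh, neck.cll, lm, pconfig)
        except NeckSSMError as exc:
            log("patient_failed", patient=pid, stage="parametrize", error=str(exc))
            if not config.skip_failures:
                raise PatientPipelineError(pid, "parametrize", exc) from exc
            failed.append(pid)
            continue
        nio.write_grid(grid, out / "grids" / f"{pid}.csv")
        grids.append(grid)
        kept_ids.append(pid)
    log("parametrized", n=len(grids))

    cohort = cohort_from_grids(grids, kept_ids)
    nio.write_cohort(cohort, out / "cohort.csv")
    model = fit_ssm(cohort)
    nio.write_model(model, out / "model.json")
    log("fitted", n_components=model.n_components)

    for pc in range(min(config.n_mode_meshes, model.n_components)):
        for s in config.mode_sd:
            mm = mode_mesh(model, pc, s)
            nio.write_mesh(mm.mesh, out / "modes" / f"pc{pc + 1}_sd{s:+.0f}.ply")
    log("modes_written", n=min(config.n_mode_meshes, model.n_components))

    report = evaluate_all(cohort, config.k_values,
                          n_samples=config.specificity_samples, seed=config.seed)
    nio.write_report(report, out / "report.json")
    nio.report_to_csv(report, out / "report.csv")
    log("evaluated", k_values=list(config.k_values))

    manifest = {
        "config_hash": cfg_hash,
        "config": _jsonable(dataclasses.asdict(config)),
        "n_patients": cohort.n,
        "n_components": model.n_components,
        "failed_patients": failed,
        "artifacts": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log("done")
    return manifest
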