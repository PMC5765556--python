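"""End-to-end orchestration: specimen -> morphometrics -> simulation -> summary.

A :class:`RunConfig` names exactly one specimen source — a synthetic preset,
a TIFF image stack, or an STL surface — plus material, load and solver
settings.  :func:`run_specimen` executes the full workflow for one specimen
and writes machine-readable artifacts; :func:`run_batch` aggregates several
specimens into a batch table with per-phenotype summaries.

Runs are deterministic given (config, seed): geometry generation is
deterministic, stage seeds are derived from the master seed, and summary
files contain no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .voxel_io import VoxelVolume, read_image_stack, read_stl, voxelize_mesh, write_image_stack
from .synthetic_fang import FangGroundTruth, generate_fang, phenotype_presets, voxel_size_for_arc_elements
from .morphometrics import full_report, MorphometricsReport
from .fem import MaterialModel, run_load_pair, effective_modulus, LoadCase
from .mechanics import (
    read_compression_record, to_stress_strain, summarize_test, theoretical_rod_stress,
)

logger = logging.getLogger("fangmech")

__all__ = ["RunConfig", "SpecimenRecord", "run_specimen", "run_batch"]


@dataclass
class RunConfig:
    """Configuration of one specimen run.  Exactly one of ``preset``,
    ``stack`` or ``stl`` must be given."""

    specimen_id: str = "specimen"
    preset: str | None = None          # name of a phenotype preset
    stack: str | None = None           # glob of TIFF slices
    stl: str | None = None             # STL surface path
    voxel_size: float | None = None    # μm; required for stack/stl
    n_arc: int = 100                   # synthetic resolution: voxels along the arc
    landmarks: str | dict | None = None  # JSON path or dict (stack/stl sources)
    skull_length: float | None = None
    youngs_modulus: float = 20e9       # Pa
    poisson_ratio: float = 0.3
    load_magnitude: float = 5.0        # N
    coarsen: int = 1
    tol: float = 1e-8
    max_iter: int = 2000
    percentile: float = 10.0
    solver: str = "auto"
    compression_record: str | None = None
    out_dir: str | None = None
    seed: int = 0
    write_fields: bool = False         # export stress/displacement stacks

    def __post_init__(self) -> None:
        sources = [s is not None for s in (self.preset, self.stack, self.stl)]
        if sum(sources) != 1:
            raise ValueError("exactly one specimen source (preset | stack | stl) required")
        if self.preset is None and self.voxel_size is None:
            raise ValueError("voxel_size is required for stack or STL sources")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SpecimenRecord:
    """One row of the batch table."""

    specimen_id: str
    phenotype: str
    morphometrics: MorphometricsReport
    parallel_stress: float            # top-decile Von Mises, Pa
    lateral_stress: float             # top-decile Von Mises, Pa
    stress_ratio: float               # lateral / parallel
    theoretical_stress: float         # straight-rod prediction, Pa
    effective_modulus: float          # Pa, from the axial simulation
    mechanical_summary: dict | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {"specimen_id": self.specimen_id, "phenotype": self.phenotype}
        row.update(self.morphometrics.to_dict())
        row.update({
            "parallel_stress": self.parallel_stress,
            "lateral_stress": self.lateral_stress,
            "stress_ratio": self.stress_ratio,
            "theoretical_stress": self.theoretical_stress,
            "effective_modulus": self.effective_modulus,
        })
        if self.mechanical_summary:
            row.update({f"test_{k}": v for k, v in self.mechanical_summary.items()})
        return row


def _load_specimen(config: RunConfig):
    """Resolve the specimen source to (volume, landmarks, phenotype, skull)."""
    if config.preset is not None:
        presets = {t.name: t for t in phenotype_presets()}
        if config.preset not in presets:
            raise KeyError(f"unknown preset {config.preset!r}; "
                           f"available: {sorted(presets)}")
        truth = presets[config.preset]
        vs = config.voxel_size or voxel_size_for_arc_elements(truth, config.n_arc)
        volume, landmarks = generate_fang(truth, vs)
        return volume, landmarks, truth.phenotype, config.skull_length or truth.skull_length
    if config.stack is not None:
        volume = read_image_stack(config.stack, config.voxel_size)
    else:
        volume = voxelize_mesh(read_stl(config.stl), config.voxel_size)
    landmarks = config.landmarks
    if isinstance(landmarks, str):
        with open(landmarks) as fh:
            landmarks = json.load(fh)
    if landmarks is None:
        raise ValueError("stack/STL sources require a landmarks file or dict")
    landmarks = {k: (np.asarray(v, float) if not isinstance(v, str) else v)
                 for k, v in landmarks.items()}
    phenotype = landmarks.get("phenotype", "unknown")
    return volume, landmarks, phenotype, config.skull_length or 1.0


def run_specimen(config: RunConfig) -> SpecimenRecord:
    """Run the full workflow for one specimen and write its artifacts."""
    volume, landmarks, phenotype, skull_length = _load_specimen(config)
    report = full_report(volume, landmarks["polyline"], skull_length)

    material = MaterialModel(config.youngs_modulus, config.poisson_ratio)
    res_par, res_lat, ratio = run_load_pair(
        volume, landmarks, material, magnitude=config.load_magnitude,
        coarsen=config.coarsen, percentile=config.percentile,
        tol=config.tol, max_iter=config.max_iter, method=config.solver,
    )
    envelope_area = np.pi * (report.mid_diameter / 2.0) ** 2
    par_case = LoadCase(config.load_magnitude, res_par.diagnostics["applied_force"],
                        mode="parallel")
    e_eff = effective_modulus(res_par, par_case, envelope_area, report.fang_length)
    sigma_theory = theoretical_rod_stress(config.load_magnitude,
                                          report.mid_diameter / 2.0, report.bvtv)

    mech = None
    if config.compression_record is not None:
        rec = read_compression_record(config.compression_record)
        curve = to_stress_strain(rec, envelope_area, report.fang_length)
        mech = summarize_test(curve, report.bvtv).to_dict()

    record = SpecimenRecord(
        specimen_id=config.specimen_id,
        phenotype=phenotype,
        morphometrics=report,
        parallel_stress=res_par.top_decile_stress,
        lateral_stress=res_lat.top_decile_stress,
        stress_ratio=ratio,
        theoretical_stress=sigma_theory,
        effective_modulus=e_eff,
        mechanical_summary=mech,
        diagnostics={
            "parallel": {k: v for k, v in res_par.diagnostics.items()
                         if np.isscalar(v) or isinstance(v, str)},
            "lateral": {k: v for k, v in res_lat.diagnostics.items()
                        if np.isscalar(v) or isinstance(v, str)},
        },
    )

    if config.out_dir:
        _write_artifacts(config, record, volume, res_par, res_lat)
    return record


def _write_artifacts(config: RunConfig, record: SpecimenRecord,
                     volume: VoxelVolume, res_par, res_lat) -> None:
    out = os.path.join(config.out_dir, config.specimen_id)
    os.makedirs(out, exist_ok=True)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(record.to_row(), fh, indent=1, sort_keys=True, default=float)
    with open(os.path.join(out, "provenance.json"), "w") as fh:
        from . import __version__
        json.dump({"config": dataclasses.asdict(config),
                   "config_digest": config.digest(),
                   "seed": config.seed,
                   "fangmech_version": __version__,
                   "numpy_version": np.__version__},
                  fh, indent=1, sort_keys=True, default=str)
    if config.write_fields:
        for tag, res in (("parallel", res_par), ("lateral", res_lat)):
            write_image_stack(
                VoxelVolume(_vm_field(volume, res), volume.voxel_size, volume.origin),
                os.path.join(out, f"von_mises_{tag}"),
            )
            for ax, comp in enumerate("xyz"):
                write_image_stack(
                    VoxelVolume(_node_field(volume, res, ax), volume.voxel_size,
                                volume.origin),
                    os.path.join(out, f"displacement_{comp}_{tag}"),
                )
    logger.info("wrote artifacts for %s to %s", config.specimen_id, out)


def _vm_field(volume: VoxelVolume, result) -> np.ndarray:
    field_ = np.zeros(volume.shape, dtype=np.float32)
    mask = volume.material_mask()
    if mask.sum() == len(result.von_mises):
        field_[mask] = result.von_mises.astype(np.float32)
    return field_


def _node_field(volume: VoxelVolume, result, axis: int) -> np.ndarray:
    """Per-voxel displacement component (μm), sampled at the element's
    first corner node."""
    field_ = np.zeros(volume.shape, dtype=np.float32)
    mask = volume.material_mask()
    if mask.sum() != len(result.von_mises):
        return field_
    shape = volume.shape
    elems = np.argwhere(mask)
    nid = (elems[:, 0] * (shape[1] + 1) + elems[:, 1]) * (shape[2] + 1) + elems[:, 2]
    lookup = {g: i for i, g in enumerate(result.node_ids)}
    rows = np.array([lookup[g] for g in nid])
    field_[mask] = result.displacements[rows, axis].astype(np.float32)
    return field_


def run_batch(configs: list[RunConfig], out_dir: str | None = None,
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run several specimens; aggregate rows and per-phenotype summaries.

    Individual failures are logged and skipped; the batch continues.
    Returns (rows, per-phenotype mean/sd summary).
    """
    if not configs:
        raise ValueError("empty batch")
    rows, failures = [], []
    for cfg in configs:
        try:
            rows.append(run_specimen(cfg).to_row())
        except Exception as exc:  # noqa: BLE001 - batch resilience
            logger.error("specimen %s failed: %s", cfg.specimen_id, exc)
            failures.append((cfg.specimen_id, str(exc)))
    if not rows:
        raise RuntimeError(f"all specimens failed: {failures}")
    table = pd.DataFrame(rows)
    numeric = table.select_dtypes("number").columns
    summary = table.groupby("phenotype")[list(numeric)].agg(["mean", "std"])
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        table.to_csv(os.path.join(out_dir, "batch.csv"), index=False)
        summary.to_csv(os.path.join(out_dir, "phenotype_summary.csv"))
        scatter_cols = ["specimen_id", "phenotype", "mid_diameter",
                        "parallel_stress", "lateral_stress", "theoretical_stress"]
        table[[c for c in scatter_cols if c in table.columns]].to_csv(
            os.path.join(out_dir, "stress_scatter.csv"), index=False)
    if failures:
        logger.warning("batch finished with %d failures: %s", len(failures), failures)
    table.attrs["failures"] = failures
    return table, summary
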