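"""Orchestration, configuration and format plumbing.

Ties the stages together: simulate -> fMRI metrics -> retinal biometrics ->
cohort statistics -> two-stage association -> JSON run report.  File formats
are NIfTI-1 for volumes/maps, CSV for tables, PNG for 2-D masks and
JSON/YAML for configs and manifests.  All voxel indices are 0-based and
world (mm) coordinates follow the NIfTI affine convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import association, cohort_stats, fmri, retina, synthetic
from .errors import ConfigurationError, FormatError, InputError

logger = logging.getLogger(__name__)
__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# NIfTI / table / mask round-tripping
# ---------------------------------------------------------------------------

def save_volume(vol: fmri.VoxelTimeSeriesVolume | fmri.MetricMap, path: str | Path) -> Path:
    """Write a 4-D time-series volume (TR stored in the 4th zoom) or a 3-D
    metric map as NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data), np.asarray(vol.affine))
    if isinstance(vol, fmri.VoxelTimeSeriesVolume):
        zooms = img.header.get_zooms()[:3] + (float(vol.tr),)
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    img.to_filename(str(path))
    return path


def load_volume(path: str | Path, expect_4d: bool = True) -> fmri.VoxelTimeSeriesVolume:
    """Load a 4-D NIfTI series; TR is read from the 4th pixdim."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(float)
    if expect_4d and data.ndim != 4:
        raise InputError(f"{path}: expected a 4-D series, got shape {data.shape}")
    tr = float(img.header.get_zooms()[3]) if data.ndim == 4 else 0.0
    return fmri.VoxelTimeSeriesVolume(data=data, affine=img.affine, tr=tr)


def load_map(path: str | Path, metric_name: str = "map") -> fmri.MetricMap:
    """Load a 3-D NIfTI map."""
    try:
        img = nib.load(str(Path(path)))
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 3-D map, got shape {data.shape}")
    return fmri.MetricMap(data=data, affine=img.affine, metric_name=metric_name)


def save_map(metric_map: fmri.MetricMap, path: str | Path) -> Path:
    return save_volume(metric_map, path)


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit PNG (255 = foreground)."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
    return path


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG as a boolean mask (nonzero = foreground)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Top-level pipeline configuration (one YAML/JSON document)."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    run_metrics: bool = True
    run_retina: bool = True
    run_cohort_stats: bool = True
    run_association: bool = True
    band_hz: tuple[float, float] = fmri.DEFAULT_BAND
    n_discard: int = fmri.DEFAULT_N_DISCARD
    fwhm_mm: float = 0.0  # smoothing off for functional maps by default
    gm_threshold: float = fmri.GM_MASK_THRESHOLD
    alpha: float = association.DEFAULT_ALPHA
    n_perm: int = association.DEFAULT_N_PERM
    bonferroni_m: int = association.BONFERRONI_M
    pairs: list[tuple[str, str]] = field(default_factory=lambda: [
        ("HC", "SCD"), ("HC", "MCI"), ("HC", "AD")])
    metrics: tuple[str, ...] = ("FALFF",)
    scores: tuple[str, ...] = ("BDST",)
    biometrics: tuple[str, ...] = ("faz_area_mm2",)
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)

    def validate(self) -> None:
        if not (0 < self.alpha <= 1):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.n_perm < 1:
            raise ConfigurationError(f"n_perm must be >= 1, got {self.n_perm}")
        if not (0 <= self.gm_threshold <= 1):
            raise ConfigurationError(
                f"gm_threshold must be in [0, 1], got {self.gm_threshold}")
        if self.fwhm_mm < 0:
            raise ConfigurationError(f"fwhm_mm must be >= 0, got {self.fwhm_mm}")
        self.cohort.validate()


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON) document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    cohort_doc = doc.pop("cohort", {})
    cohort = synthetic.CohortConfig()
    for key, val in cohort_doc.items():
        if key == "grid":
            cohort.grid = synthetic.GridSpec(**{
                k: tuple(v) if k == "shape" else v for k, v in val.items()})
        elif key == "retina":
            cohort.retina = synthetic.RetinaSpec(**val)
        elif key == "effects":
            cohort.effects = [synthetic.PlantedEffect(**{
                k: tuple(v) if k == "blob_center" and v is not None else v
                for k, v in e.items()}) for e in val]
        elif hasattr(cohort, key):
            setattr(cohort, key, val)
        else:
            raise ConfigurationError(f"cohort: unknown field {key!r}")
    cfg = RunConfig(cohort=cohort)
    for key, val in doc.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown config field {key!r}")
        if key == "pairs":
            val = [tuple(p) for p in val]
        elif key in ("band_hz", "metrics", "scores", "biometrics"):
            val = tuple(val)
        setattr(cfg, key, val)
    cfg.cohort.seed = cfg.cohort.seed or cfg.seed
    return cfg


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def simulate_cohort_to_disk(config: synthetic.CohortConfig, out_dir: str | Path,
                            write_fmri: bool = True) -> dict:
    """Generate the cohort and write every artifact; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = synthetic.generate_cohort(config)
    table = synthetic.subjects_table(cohort)
    table.to_csv(out / "subjects.csv", index=False)
    thickness = synthetic.cohort_thickness_table(cohort, config)
    thickness.insert(0, "subject_id", [r.subject_id for r in cohort])
    thickness.to_csv(out / "thickness.csv", index=False)
    manifest = {"n_subjects": len(cohort), "seed": config.seed,
                "subjects_csv": "subjects.csv", "thickness_csv": "thickness.csv",
                "subjects": []}
    for rec in cohort:
        sdir = out / rec.subject_id
        sdir.mkdir(exist_ok=True)
        entry = {"subject_id": rec.subject_id, "group": rec.group}
        if write_fmri:
            vol, gm, motion = synthetic.generate_fmri(rec, config)
            save_volume(vol, sdir / "func.nii")
            nib.Nifti1Image(gm, vol.affine).to_filename(str(sdir / "gm_prob.nii"))
            motion.to_csv(sdir / "motion.csv", index=False)
            entry.update(func="func.nii", gm_prob="gm_prob.nii", motion="motion.csv")
        eye = synthetic.generate_retina(rec, config)
        save_mask_png(eye.vessel_mask, sdir / "vessels.png")
        save_mask_png(eye.faz_mask, sdir / "faz.png")
        for name, arr in eye.thickness_maps.items():
            np.savetxt(sdir / f"thickness_{name}.csv", arr, delimiter=",", fmt="%.3f")
        entry.update(vessels="vessels.png", faz="faz.png",
                     quality_index=eye.quality_index,
                     pixel_size_mm=eye.pixel_size_mm)
        rec.paths = {k: str(sdir / v) for k, v in entry.items()
                     if isinstance(v, str) and k not in ("subject_id", "group")}
        manifest["subjects"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def analyze_cohort(
    cohort_cfg: synthetic.CohortConfig,
    *,
    score: str = "BDST",
    biometric: str = "faz_area_mm2",
    metric: str = "FALFF",
    alpha: float = association.DEFAULT_ALPHA,
    n_perm: int = association.DEFAULT_N_PERM,
    seed: int = 0,
    measure_eyes: bool = True,
) -> dict:
    """In-memory end-to-end analysis of one simulated cohort.

    Generates the cohort, computes per-subject metric maps and the group
    gray-matter mask, measures the ophthalmic biometric from the generated
    retinal images (or falls back to the planted target values when
    ``measure_eyes`` is False), and runs the two-stage association for the
    pooled cohort.  Returns the stage-1/stage-2 masks plus the tables, for
    calibration and recovery studies.
    """
    cohort = synthetic.generate_cohort(cohort_cfg)
    table = synthetic.subjects_table(cohort)
    maps, gm_maps = [], []
    for rec in cohort:
        vol, gm, motion = synthetic.generate_fmri(rec, cohort_cfg)
        gm_maps.append(gm)
        maps.append(fmri.compute_subject_metric_maps(
            vol, motion, gm, metrics=(metric,))[metric])
    gm_mask = fmri.build_group_gm_mask(gm_maps)
    if measure_eyes:
        vals = []
        for rec in cohort:
            eye = synthetic.generate_retina(rec, cohort_cfg)
            if biometric == "faz_area_mm2":
                vals.append(retina.faz_area(
                    retina.clean_components(eye.faz_mask), eye.pixel_size_mm))
            elif biometric == "faz_perimeter_mm":
                vals.append(retina.faz_perimeter(
                    retina.clean_components(eye.faz_mask), eye.pixel_size_mm))
            elif biometric == "rbvc_per_mm":
                vals.append(retina.rbvc(retina.clean_components(eye.vessel_mask),
                                        eye.pixel_size_mm)[1])
            else:
                key = {"rnfl_thickness_um": "RNFL",
                       "gcl_ipl_thickness_um": "GCL-IPL"}[biometric]
                vals.append(retina.layer_thickness_mean(eye.thickness_maps[key]))
        bio = np.asarray(vals)
    else:
        bio = table[f"target_{biometric}"].to_numpy()
    cov = table[list(association.FUNCTIONAL_COVARIATES)]
    rng = np.random.default_rng(seed)
    m1 = association.stage1_voxelwise(maps, table[score].to_numpy(), cov,
                                      gm_mask, alpha=alpha, n_perm=n_perm, seed=rng)
    m2, fits = (association.stage2(maps, bio, cov, m1, alpha=alpha,
                                   n_perm=n_perm, seed=rng)
                if m1.n_selected else (None, []))
    return {"stage1": m1, "stage2": m2, "fits": fits, "subjects": table,
            "gm_mask": gm_mask, "metric_maps": maps, "biometric": bio}


def _payload_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in order and write ``report.json``.

    Returns the report dict; any stage failure raises with the stage name in
    the message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": config.seed, "stages": {},
              "warnings": [], "n_association_runs": 0}
    cohort_cfg = config.cohort
    if not cohort_cfg.seed:
        cohort_cfg.seed = config.seed

    try:
        cohort = synthetic.generate_cohort(cohort_cfg)
        subjects = synthetic.subjects_table(cohort)
        if config.simulate:
            simulate_cohort_to_disk(cohort_cfg, out / "cohort",
                                    write_fmri=config.run_metrics)
            report["stages"]["simulate"] = {"n_subjects": len(cohort),
                                            "dir": "cohort"}
    except Exception as exc:
        raise type(exc)(f"[simulate] {exc}") from exc

    metric_maps: dict[str, list] = {}
    gm_mask = None
    affine = cohort_cfg.grid.affine
    if config.run_metrics:
        try:
            gm_maps = []
            maps_by_metric = {m: [] for m in config.metrics}
            for rec in cohort:
                vol, gm, motion = synthetic.generate_fmri(rec, cohort_cfg)
                gm_maps.append(gm)
                maps = fmri.compute_subject_metric_maps(
                    vol, motion, gm,
                    n_discard=config.n_discard, band=config.band_hz,
                    fwhm_mm=config.fwhm_mm, metrics=tuple(config.metrics))
                for m in config.metrics:
                    maps_by_metric[m].append(maps[m])
            gm_mask = fmri.build_group_gm_mask(gm_maps, config.gm_threshold)
            metric_maps = maps_by_metric
            report["stages"]["metrics"] = {
                "metrics": list(config.metrics),
                "gm_mask_voxels": int(gm_mask.sum())}
        except Exception as exc:
            raise type(exc)(f"[metrics] {exc}") from exc

    if config.run_retina:
        try:
            bio_rows = []
            for rec in cohort:
                eye = synthetic.generate_retina(rec, cohort_cfg)
                if not retina.quality_gate(eye):
                    report["warnings"].append(
                        f"{rec.subject_id}: failed quality gate")
                    continue
                bio = retina.compute_biometrics(eye)
                bio_rows.append({"subject_id": rec.subject_id, **bio.as_dict()})
            biometrics = pd.DataFrame(bio_rows)
            biometrics.to_csv(out / "biometrics.csv", index=False)
            subjects = subjects.merge(biometrics, on="subject_id")
            report["stages"]["retina"] = {"n_eyes": len(biometrics),
                                          "csv": "biometrics.csv"}
        except Exception as exc:
            raise type(exc)(f"[retina] {exc}") from exc

    if config.run_cohort_stats:
        try:
            stats_table = cohort_stats.summarize_cohort(subjects)
            stats_table.to_csv(out / "cohort_stats.csv", index=False)
            report["stages"]["cohort_stats"] = {
                "csv": "cohort_stats.csv",
                "rows": stats_table.to_dict(orient="records")}
        except Exception as exc:
            raise type(exc)(f"[cohort_stats] {exc}") from exc

    if config.run_association:
        try:
            thickness = synthetic.cohort_thickness_table(cohort, cohort_cfg)
            pair_reports = []
            for i, pair in enumerate(config.pairs):
                rep = association.run_group_pair_analysis(
                    subjects, pair,
                    metric_maps=metric_maps or None,
                    thickness=thickness,
                    gm_mask=gm_mask, affine=affine,
                    scores=tuple(config.scores),
                    biometrics=tuple(config.biometrics),
                    alpha=config.alpha, n_perm=config.n_perm,
                    seed=config.seed + 1000 + i)
                pair_reports.append(rep)
                report["n_association_runs"] += len(rep["results"])
            report["stages"]["association"] = {"pairs": pair_reports}
        except Exception as exc:
            raise type(exc)(f"[association] {exc}") from exc

    report["payload_hash"] = _payload_hash(
        {k: v for k, v in report.items() if k != "payload_hash"})
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
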