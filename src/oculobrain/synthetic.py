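"""Synthetic multimodal cohort generator.

Emulates the study's cohort structure and data channels so the whole
pipeline is testable without any acquisition: 76 subjects in four groups
(HC 16, SCD 35, MCI 18, AD 7) with demographic covariates, cognitive
scores, post-realignment resting-state fMRI volumes on a common grid,
gray-matter probability maps, motion-parameter tables, OCTA-style retinal
segmentation masks and layer-thickness maps, and 62-ROI DKT cortical
thickness tables.

A *planted effect* couples a per-subject latent variable (with per-group
mean shifts) simultaneously to (a) a brain signal -- the in-band sinusoid
amplitude (FALFF channel) or shared-signal fraction (ReHo channel) inside a
voxel blob, or a DKT ROI thickness shift, (b) one cognitive score, and
(c) one ophthalmic biometric.  With all slopes zero every channel is pure
noise around its group baseline, giving an exact global null.

All randomness derives from ``CohortConfig.seed`` through per-subject,
per-channel ``numpy`` seed sequences, so identical configs reproduce
byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from . import dkt
from .errors import ConfigurationError, GenerationError
from .fmri import VoxelTimeSeriesVolume, bandpass_filter
from .retina import RetinalImageSet

GROUPS = ("HC", "SCD", "MCI", "AD")

#: Group sizes of the emulated cohort (HC, SCD, MCI, AD).
DEFAULT_GROUP_SIZES = {"HC": 16, "SCD": 35, "MCI": 18, "AD": 7}

#: Per-group demographic distributions: age mean/SD as printed in the
#: cohort table; sex / hypertension / diabetes probabilities equal to the
#: printed counts divided by group size; education and ETIV chosen as
#: plausible for an elderly memory-clinic sample.
DEFAULT_DEMOGRAPHICS = {
    "HC": dict(age_mean=66.63, age_sd=4.559, p_male=5 / 16, p_hyp=2 / 16,
               p_dia=2 / 16, edu_mean=13.0, edu_sd=2.2,
               etiv_mean=1.45e6, etiv_sd=1.4e5),
    "SCD": dict(age_mean=65.91, age_sd=4.161, p_male=7 / 35, p_hyp=15 / 35,
                p_dia=2 / 35, edu_mean=13.0, edu_sd=2.2,
                etiv_mean=1.45e6, etiv_sd=1.4e5),
    "MCI": dict(age_mean=66.22, age_sd=5.264, p_male=8 / 18, p_hyp=5 / 18,
                p_dia=3 / 18, edu_mean=11.3, edu_sd=2.2,
                etiv_mean=1.45e6, etiv_sd=1.4e5),
    "AD": dict(age_mean=64.57, age_sd=5.192, p_male=3 / 7, p_hyp=1 / 7,
               p_dia=0 / 7, edu_mean=10.9, edu_sd=2.2,
               etiv_mean=1.45e6, etiv_sd=1.4e5),
}

COGNITIVE_SCORES = ("MMSE", "MoCA", "BNT", "CDT", "BDST", "TMT-A", "TMT-B")

#: Per-group score baselines (anchored to the printed per-group medians) and
#: within-group noise SDs, on each score's native scale.
DEFAULT_SCORE_BASELINES = {
    "MMSE": {"HC": 28.6, "SCD": 28.9, "MCI": 27.0, "AD": 17.0},
    "MoCA": {"HC": 25.6, "SCD": 26.0, "MCI": 22.6, "AD": 13.6},
    "BNT": {"HC": 25.6, "SCD": 27.0, "MCI": 24.0, "AD": 21.4},
    "CDT": {"HC": 3.8, "SCD": 3.9, "MCI": 3.8, "AD": 2.1},
    "BDST": {"HC": 4.8, "SCD": 4.7, "MCI": 4.0, "AD": 3.6},
    "TMT-A": {"HC": 48.0, "SCD": 45.0, "MCI": 58.0, "AD": 115.0},
    "TMT-B": {"HC": 80.0, "SCD": 67.0, "MCI": 100.0, "AD": 180.0},
}
DEFAULT_SCORE_NOISE_SD = {
    "MMSE": 1.2, "MoCA": 1.8, "BNT": 2.0, "CDT": 0.7, "BDST": 1.0,
    "TMT-A": 14.0, "TMT-B": 28.0,
}

OCULAR_BIOMETRICS = ("faz_area_mm2", "faz_perimeter_mm", "rbvc_per_mm",
                     "rnfl_thickness_um", "gcl_ipl_thickness_um")


@dataclass
class GridSpec:
    """fMRI grid: deliberately desk-scale (full pipelines run in minutes)."""

    shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 3.0
    tr: float = 2.0
    n_volumes: int = 185

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -np.asarray(self.shape) * self.voxel_size_mm / 2.0
        return aff


@dataclass
class RetinaSpec:
    """Geometry of the synthetic 3x3 mm OCTA en-face images."""

    image_size: int = 256
    pixel_size_mm: float = 3.0 / 256
    n_vessels: int = 14
    faz_base_area_mm2: float = 0.36
    tortuosity_base_px: float = 1.5
    tortuosity_wavelength_px: float = 60.0
    vessel_halfwidth_px: int = 2
    rnfl_base_um: float = 95.0
    gcl_ipl_base_um: float = 82.0


@dataclass
class PlantedEffect:
    """A latent coupling among a brain target, a cognitive score and an
    ophthalmic biometric.

    The subject latent is ``N(group_modulation[group], 1)``.  The brain
    signal scales as ``brain_slope * latent`` (so a latent of exactly 0
    produces no signal at all); the cognitive score adds
    ``cognitive_slope * (latent - group_modulation[group])`` on top of its
    per-group baseline; the ophthalmic target adds
    ``ocular_slope * (latent - group_modulation["HC"])`` to its base so the
    HC mean stays at base while disease groups shift.
    """

    latent_name: str = "neurodegeneration"
    brain_channel: str = "falff-amplitude"  # | "reho-coherence" | "thickness"
    blob_center: tuple[int, int, int] | None = (10, 10, 6)
    blob_radius_vox: float = 2.0
    roi_label: str | None = None
    brain_slope: float = 0.0
    signal_freq_hz: float = 0.05
    cognitive_score: str = "BDST"
    cognitive_slope: float = 0.0
    ocular_biometric: str = "faz_area_mm2"
    ocular_slope: float = 0.0
    group_modulation: dict[str, float] = field(
        default_factory=lambda: {"HC": 3.0, "SCD": 2.5, "MCI": 1.8, "AD": 1.0})


def default_planted_effect() -> PlantedEffect:
    """The default study-condition coupling: a FALFF-amplitude blob driven by
    a latent that also lowers the backward digit span and enlarges the FAZ as
    the latent decreases (slope values fixed by a one-off design simulation
    at n = 76; see the methods note)."""
    return PlantedEffect(
        brain_channel="falff-amplitude",
        blob_center=(10, 10, 6), blob_radius_vox=2.0,
        brain_slope=0.45,
        cognitive_score="BDST", cognitive_slope=1.0,
        ocular_biometric="faz_area_mm2", ocular_slope=-0.05,
    )


@dataclass
class CohortConfig:
    """Everything needed to generate a deterministic synthetic cohort."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    demographics: dict[str, dict] = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_DEMOGRAPHICS.items()})
    score_baselines: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_SCORE_BASELINES.items()})
    score_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_NOISE_SD))
    effects: list[PlantedEffect] = field(default_factory=lambda: [default_planted_effect()])
    fmri_noise_sd: float = 1.0
    ocular_noise_sd: dict[str, float] = field(default_factory=lambda: {
        "faz_area_mm2": 0.012, "rbvc_per_mm": 0.0,
        "rnfl_thickness_um": 3.0, "gcl_ipl_thickness_um": 3.0})
    thickness_baseline_mm: float = 2.5
    thickness_noise_sd: float = 0.08
    grid: GridSpec = field(default_factory=GridSpec)
    retina: RetinaSpec = field(default_factory=RetinaSpec)
    round_scores: bool = False
    seed: int = 0
    n_discard: int = 10

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"group_sizes: unknown group {g!r}")
            if n <= 0:
                raise ConfigurationError(f"group_sizes[{g!r}] must be > 0, got {n}")
        if self.grid.tr <= 0:
            raise ConfigurationError(f"grid.tr must be > 0, got {self.grid.tr}")
        if self.retina.pixel_size_mm <= 0:
            raise ConfigurationError(
                f"retina.pixel_size_mm must be > 0, got {self.retina.pixel_size_mm}")
        if self.grid.n_volumes <= self.n_discard:
            raise ConfigurationError(
                f"grid.n_volumes ({self.grid.n_volumes}) must exceed "
                f"n_discard ({self.n_discard})")
        shape = np.asarray(self.grid.shape)
        for eff in self.effects:
            if not np.isfinite([eff.brain_slope, eff.cognitive_slope,
                                eff.ocular_slope]).all():
                raise ConfigurationError("effects: slopes must be finite")
            if eff.brain_channel not in ("falff-amplitude", "reho-coherence",
                                         "thickness"):
                raise ConfigurationError(
                    f"effects: unknown brain_channel {eff.brain_channel!r}")
            if eff.brain_channel == "thickness":
                if eff.roi_label is None:
                    raise ConfigurationError(
                        "effects: thickness channel requires roi_label")
                try:
                    dkt.validate_label(eff.roi_label)
                except KeyError as exc:
                    raise ConfigurationError(f"effects: {exc}") from exc
            elif eff.blob_center is not None:
                c = np.asarray(eff.blob_center)
                if (c - eff.blob_radius_vox < 0).any() or \
                        (c + eff.blob_radius_vox >= shape).any():
                    raise ConfigurationError(
                        f"effects: blob {tuple(eff.blob_center)} r={eff.blob_radius_vox} "
                        f"does not lie inside grid {tuple(self.grid.shape)}")
            if eff.cognitive_score not in COGNITIVE_SCORES:
                raise ConfigurationError(
                    f"effects: unknown cognitive_score {eff.cognitive_score!r}")
            if eff.ocular_biometric not in OCULAR_BIOMETRICS:
                raise ConfigurationError(
                    f"effects: unknown ocular_biometric {eff.ocular_biometric!r}")


@dataclass
class SubjectRecord:
    """One synthetic participant; imaging is generated on demand from the
    per-subject seed so large 4-D arrays never need to be held for the whole
    cohort at once."""

    subject_id: str
    group: str
    age: float
    sex: int  # 0 = female, 1 = male
    education: float
    hypertension: int
    diabetes: int
    etiv: float
    scores: dict[str, float]
    latents: dict[str, float]
    ocular_targets: dict[str, float]
    index: int
    paths: dict[str, str] = field(default_factory=dict)


def _subject_rng(config: CohortConfig, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed), int(index), int(stream)]))


# ---------------------------------------------------------------------------
# Cohort-level generation
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate all subject records (covariates, latents, scores and scalar
    ophthalmic targets).  Deterministic given ``config.seed``."""
    config.validate()
    records: list[SubjectRecord] = []
    index = 0
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        demo = config.demographics[group]
        for _ in range(n):
            rng = _subject_rng(config, index, 0)
            latents = {
                eff.latent_name: float(eff.group_modulation[group] + rng.normal())
                for eff in config.effects
            }
            scores = {}
            for score in COGNITIVE_SCORES:
                val = config.score_baselines[score][group]
                for eff in config.effects:
                    if eff.cognitive_score == score:
                        val += eff.cognitive_slope * (
                            latents[eff.latent_name] - eff.group_modulation[group])
                val += rng.normal(0.0, config.score_noise_sd[score])
                if config.round_scores:
                    val = float(np.round(val))
                scores[score] = float(val)
            ocular = {
                "faz_area_mm2": config.retina.faz_base_area_mm2,
                "rbvc_per_mm": 0.0,  # base tortuosity set by RetinaSpec
                "rnfl_thickness_um": config.retina.rnfl_base_um,
                "gcl_ipl_thickness_um": config.retina.gcl_ipl_base_um,
            }
            for eff in config.effects:
                if eff.ocular_biometric in ocular:
                    ocular[eff.ocular_biometric] += eff.ocular_slope * (
                        latents[eff.latent_name] - eff.group_modulation["HC"])
            for name, sd in config.ocular_noise_sd.items():
                if name in ocular and sd > 0:
                    ocular[name] += rng.normal(0.0, sd)
            ocular["faz_area_mm2"] = max(ocular["faz_area_mm2"], 0.05)
            records.append(SubjectRecord(
                subject_id=f"sub-{index:03d}",
                group=group,
                age=float(rng.normal(demo["age_mean"], demo["age_sd"])),
                sex=int(rng.random() < demo["p_male"]),
                education=float(np.clip(rng.normal(demo["edu_mean"], demo["edu_sd"]), 6, 22)),
                hypertension=int(rng.random() < demo["p_hyp"]),
                diabetes=int(rng.random() < demo["p_dia"]),
                etiv=float(rng.normal(demo["etiv_mean"], demo["etiv_sd"])),
                scores=scores,
                latents=latents,
                ocular_targets=ocular,
                index=index,
            ))
            index += 1
    return records


def subjects_table(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten the cohort to one row per subject (covariates + scores +
    ground-truth ophthalmic targets)."""
    rows = []
    for rec in cohort:
        row = {
            "subject_id": rec.subject_id, "group": rec.group, "age": rec.age,
            "sex": rec.sex, "education": rec.education,
            "hypertension": rec.hypertension, "diabetes": rec.diabetes,
            "etiv": rec.etiv,
        }
        row.update(rec.scores)
        row.update({f"latent_{k}": v for k, v in rec.latents.items()})
        row.update({f"target_{k}": v for k, v in rec.ocular_targets.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fMRI generation
# ---------------------------------------------------------------------------

def _brain_ellipsoid(shape: tuple[int, int, int]) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.45
    d = sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return d <= 1.0


def _blob_mask(shape, center, radius) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    d = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return d <= radius ** 2


def generate_fmri(subject: SubjectRecord, config: CohortConfig
                  ) -> tuple[VoxelTimeSeriesVolume, np.ndarray, pd.DataFrame]:
    """Per-subject 4-D volume, gray-matter probability map and motion table.

    The volume is Gaussian baseline noise; inside each planted blob an
    in-band (0.01-0.1 Hz) sinusoid with per-voxel random phase (FALFF
    channel) or a shared band-limited component (ReHo channel) is added with
    amplitude ``brain_slope * latent``.
    """
    shape = tuple(config.grid.shape)
    n_t = config.grid.n_volumes
    tr = config.grid.tr
    rng = _subject_rng(config, subject.index, 1)
    data = rng.normal(0.0, config.fmri_noise_sd, size=shape + (n_t,))
    t = np.arange(n_t) * tr

    for eff in config.effects:
        if eff.brain_channel == "thickness" or eff.blob_center is None:
            continue
        blob = _blob_mask(shape, eff.blob_center, eff.blob_radius_vox)
        if not blob.any():
            raise GenerationError(f"blob {eff.blob_center} is empty on grid {shape}")
        amp = eff.brain_slope * subject.latents[eff.latent_name]
        if amp == 0.0:
            continue
        n_blob = int(blob.sum())
        if eff.brain_channel == "falff-amplitude":
            phases = rng.uniform(0, 2 * np.pi, size=(n_blob, 1))
            sig = amp * np.sin(2 * np.pi * eff.signal_freq_hz * t[None, :] + phases)
            data[blob] += sig
        else:  # reho-coherence: one shared in-band series across the blob
            shared = bandpass_filter(rng.normal(size=n_t), tr)
            shared = shared / max(shared.std(), 1e-12)
            data[blob] += amp * shared[None, :]

    brain = _brain_ellipsoid(shape)
    gm_prob = np.where(brain, 0.85, 0.02) + rng.uniform(-0.02, 0.02, size=shape)
    gm_prob = np.clip(gm_prob, 0.0, 1.0)

    steps = rng.normal(0.0, 0.02, size=(n_t, 6))
    motion = pd.DataFrame(
        np.cumsum(steps, axis=0),
        columns=["tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg"])
    vol = VoxelTimeSeriesVolume(data=data, affine=config.grid.affine, tr=tr)
    return vol, gm_prob, motion


# ---------------------------------------------------------------------------
# Retina generation
# ---------------------------------------------------------------------------

def generate_retina(subject: SubjectRecord, config: CohortConfig) -> RetinalImageSet:
    """Per-subject synthetic OCTA image set.

    The FAZ mask is a filled, slightly eccentric ellipse whose pixel area
    matches the subject's planted FAZ-area target; vessels radiate from just
    outside the FAZ to the canvas edge with a sinusoidal perpendicular
    perturbation whose amplitude carries any planted tortuosity effect;
    layer-thickness maps are constant-plus-noise fields at the planted
    per-subject means.
    """
    spec = config.retina
    size = spec.image_size
    rng = _subject_rng(config, subject.index, 2)
    center = np.array([size / 2.0, size / 2.0])

    # --- FAZ mask: ellipse with the target pixel area -----------------------
    area_px = subject.ocular_targets["faz_area_mm2"] / spec.pixel_size_mm ** 2
    r_px = np.sqrt(area_px / np.pi)
    ecc = 1.0 + rng.uniform(-0.08, 0.08)
    theta0 = rng.uniform(0, np.pi)
    yy, xx = np.indices((size, size)).astype(float)
    dy, dx = yy - center[0], xx - center[1]
    u = dy * np.cos(theta0) + dx * np.sin(theta0)
    v = -dy * np.sin(theta0) + dx * np.cos(theta0)
    faz_mask = (u / (r_px * ecc)) ** 2 + (v / (r_px / ecc)) ** 2 <= 1.0

    # --- vessel mask: radial curves with sinusoidal perturbation ------------
    tort_amp = spec.tortuosity_base_px
    for eff in config.effects:
        if eff.ocular_biometric == "rbvc_per_mm":
            tort_amp += eff.ocular_slope * (
                subject.latents[eff.latent_name] - eff.group_modulation["HC"])
    tort_amp = max(tort_amp, 0.0)

    vessel = np.zeros((size, size), dtype=bool)
    # start outside the FAZ but far enough from the centre that adjacent
    # vessels (angular jitter included) can never merge at their origin
    r0 = max(1.3 * r_px, 0.16 * size)
    r_max = size / 2.0 - 2.0
    n_steps = int(4 * (r_max - r0))
    ts = np.linspace(0.0, 1.0, max(n_steps, 16))
    clipped = False
    spacing = 2 * np.pi / spec.n_vessels
    for k in range(spec.n_vessels):
        theta = spacing * (k + rng.uniform(-0.15, 0.15))
        phase = rng.uniform(0, 2 * np.pi)
        radial = np.array([np.cos(theta), np.sin(theta)])
        perp = np.array([-np.sin(theta), np.cos(theta)])
        rr = r0 + ts * (r_max - r0)
        arc = ts * (r_max - r0)
        offset = tort_amp * np.sin(2 * np.pi * arc / spec.tortuosity_wavelength_px + phase)
        pts = center[None, :] + rr[:, None] * radial[None, :] + offset[:, None] * perp[None, :]
        ij = np.round(pts).astype(int)
        inside = (ij[:, 0] >= 0) & (ij[:, 0] < size) & (ij[:, 1] >= 0) & (ij[:, 1] < size)
        if not inside.all():
            clipped = True
        ij = ij[inside]
        vessel[ij[:, 0], ij[:, 1]] = True
    if clipped:
        warnings.warn("vessel curve left the canvas; clipped", stacklevel=2)
    if spec.vessel_halfwidth_px > 0:
        yy0, xx0 = np.ogrid[-spec.vessel_halfwidth_px:spec.vessel_halfwidth_px + 1,
                            -spec.vessel_halfwidth_px:spec.vessel_halfwidth_px + 1]
        disk = yy0 ** 2 + xx0 ** 2 <= spec.vessel_halfwidth_px ** 2
        vessel = ndimage.binary_dilation(vessel, structure=disk)

    # --- layer-thickness maps ----------------------------------------------
    maps = {}
    for name, key in (("RNFL", "rnfl_thickness_um"), ("GCL-IPL", "gcl_ipl_thickness_um")):
        base = subject.ocular_targets[key]
        pix = rng.normal(0.0, 2.0, size=(size, size))
        maps[name] = base + pix - pix.mean()  # map mean equals the target
    return RetinalImageSet(vessel_mask=vessel, faz_mask=faz_mask,
                           thickness_maps=maps,
                           pixel_size_mm=spec.pixel_size_mm,
                           quality_index=float(rng.uniform(7.0, 10.0)))


# ---------------------------------------------------------------------------
# Cortical thickness table
# ---------------------------------------------------------------------------

def generate_thickness_table(subject: SubjectRecord, config: CohortConfig) -> pd.Series:
    """62-entry DKT ROI cortical-thickness table (mm) for one subject; a
    planted thickness effect shifts its target ROI by ``slope * latent``."""
    rng = _subject_rng(config, subject.index, 3)
    values = config.thickness_baseline_mm + rng.normal(
        0.0, config.thickness_noise_sd, size=len(dkt.DKT_LABELS))
    table = pd.Series(values, index=list(dkt.DKT_LABELS), name=subject.subject_id)
    for eff in config.effects:
        if eff.brain_channel == "thickness":
            table[eff.roi_label] += eff.brain_slope * subject.latents[eff.latent_name]
    return table


def cohort_thickness_table(cohort: list[SubjectRecord], config: CohortConfig) -> pd.DataFrame:
    """Stack per-subject thickness tables into a subjects x 62 frame."""
    return pd.DataFrame([generate_thickness_table(rec, config) for rec in cohort])


def compact_cohort_config(seed: int = 0, null: bool = False) -> CohortConfig:
    """The compact simulation-study configuration: the full 76-subject cohort
    on a 10 x 10 x 6 voxel grid (185 volumes, TR 2 s) with a radius-1.5 blob
    at the grid centre and 160-px retinal images.

    This is the configuration used by the package's calibration and recovery
    simulations; the reduced grid keeps hundreds of replicate cohorts within
    desk-scale runtimes while leaving per-voxel statistics (series length,
    subject count, effect sizes) at their defaults.  ``null=True`` zeroes
    every planted slope (exact global null).
    """
    cfg = CohortConfig(seed=seed)
    cfg.grid = GridSpec(shape=(10, 10, 6), voxel_size_mm=3.0, tr=2.0, n_volumes=185)
    cfg.retina = RetinaSpec(image_size=160, pixel_size_mm=3.0 / 160)
    eff = default_planted_effect()
    eff.blob_center = (5, 5, 3)
    eff.blob_radius_vox = 1.5
    if null:
        eff.brain_slope = eff.cognitive_slope = eff.ocular_slope = 0.0
    cfg.effects = [eff]
    return cfg


def null_config(**overrides) -> CohortConfig:
    """A config with every planted slope zero (exact global null)."""
    cfg = CohortConfig(**overrides)
    cfg.effects = [dataclasses.replace(
        default_planted_effect(), brain_slope=0.0, cognitive_slope=0.0,
        ocular_slope=0.0)]
    return cfg
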