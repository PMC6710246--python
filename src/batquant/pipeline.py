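"""Per-subject orchestration and cohort analysis.

``run_subject`` chains the four modality pipelines — PET kinetics, BAT
segmentation, water-fat MRI, thermography — for one subject and returns one
cohort row; ``run_cohort`` fits the pre-specified regression models on a
cohort table.  ``make_synthetic_subject`` builds a complete synthetic subject
(phantoms for every modality with known ground truth) so the whole chain can
run without any acquired data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batseg, fatwater, kinetics, stats, synthio, thermo

logger = logging.getLogger("batquant")

__all__ = [
    "PipelineConfig",
    "SubjectData",
    "SubjectTruth",
    "run_subject",
    "run_cohort",
    "make_synthetic_subject",
]


@dataclass
class PipelineConfig:
    """All fixed analysis constants, with study defaults.

    Thresholds: BAT segmentation keeps GUR strictly above 10 umol/100 ml/min;
    mask refinement removes FF < 0.40 and R2* > 120 1/s; fat masks keep
    FF >= 0.40.  Slice exclusions: 6 inferior + 6 superior on the resampled
    GUR grid, 3 + 3 on the multi-echo grid, and the 5 inferiormost slices of
    the aorta ROI.  Plasma-to-whole-blood ratio 1.1, lumped constant 1,
    emissivity 0.98.
    """

    gur_threshold: float = 10.0
    ff_min: float = 0.40
    r2s_max: float = 120.0
    pet_slice_exclusion: tuple[int, int] = (6, 6)
    multiecho_slice_exclusion: tuple[int, int] = (3, 3)
    idif_excluded_inferior_slices: int = 5
    plasma_ratio: float = 1.1
    lumped_constant: float = 1.0
    emissivity: float = 0.98
    n_basis: int = 50
    theta_min: float = 0.02
    theta_max: float = 1.0
    fine_step_s: float = 0.5
    frame_weighting: str = "duration"  # or "uniform"
    b0_t: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gur_threshold", "ff_min", "r2s_max", "plasma_ratio",
                     "lumped_constant", "emissivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.pet_slice_exclusion = tuple(self.pet_slice_exclusion)
        self.multiecho_slice_exclusion = tuple(self.multiecho_slice_exclusion)

    def weights(self, schedule: kinetics.FrameSchedule) -> np.ndarray:
        if self.frame_weighting == "uniform":
            return np.ones(schedule.n_frames)
        return schedule.durations_s.copy()

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["pet_slice_exclusion"] = list(self.pet_slice_exclusion)
        d["multiecho_slice_exclusion"] = list(self.multiecho_slice_exclusion)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


@dataclass
class SubjectData:
    """In-memory inputs of one subject."""

    # PET
    pet4d: np.ndarray
    schedule: kinetics.FrameSchedule
    pet_affine: np.ndarray
    aorta_mask: np.ndarray
    glucose_pre_mmol_l: float | None
    glucose_post_mmol_l: float | None
    # multi-echo MR
    multiecho_signal: np.ndarray
    multiecho_tes_ms: np.ndarray
    multiecho_affine: np.ndarray
    rough_bat_mask: np.ndarray
    # dual-echo MR
    dualecho_signal: np.ndarray
    dualecho_tes_ms: np.ndarray
    dualecho_affine: np.ndarray
    removal_mask: np.ndarray | None = None
    # IRT
    irt_raw_frames: np.ndarray | None = None
    irt_scf_mask: np.ndarray | None = None
    irt_pnr_mask: np.ndarray | None = None
    irt_env: thermo.Environment | None = None
    subject_id: int = 1


@dataclass
class SubjectTruth:
    """Ground truth attached to a synthetic subject."""

    total_bat_gur_umol_min: float
    ki: dict[int, float]
    ff: dict[int, float]
    r2s: dict[int, float]
    scf_neutral_c: float
    scf_cold_c: float
    pnr_neutral_c: float
    pnr_cold_c: float


def _voxel_size(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(v) for v in np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0)))


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %.2f s", name, t1 - t0)
    return t1


def run_subject(subject: SubjectData, config: PipelineConfig | None = None) -> dict:
    """Run the full per-subject pipeline and return one cohort row.

    Stages: IDIF extraction and plasma conversion, basis-function Ki/GUR
    mapping, resampling to the dual-echo grid, threshold segmentation and
    total GUR, multi-echo FF/R2* with mask refinement, dual-echo FF with the
    fat-mask intersection, and thermography window means.
    """
    config = config or PipelineConfig()
    if subject.glucose_pre_mmol_l is None or subject.glucose_post_mmol_l is None:
        raise ValueError("missing serum glucose value (glucose_pre/glucose_post)")

    t0 = time.perf_counter()
    # --- kinetics ---
    idif = kinetics.extract_idif(
        subject.pet4d, subject.aorta_mask, subject.schedule,
        config.idif_excluded_inferior_slices,
    )
    cp = kinetics.blood_to_plasma(idif, config.plasma_ratio, config.fine_step_s)
    basis = kinetics.build_basis(
        cp, subject.schedule, config.n_basis, config.theta_min, config.theta_max
    )
    ki = kinetics.ki_map(subject.pet4d, basis, weights=config.weights(subject.schedule))
    gur = kinetics.gur_map(
        ki,
        subject.glucose_pre_mmol_l,
        subject.glucose_post_mmol_l,
        _voxel_size(subject.pet_affine),
        config.lumped_constant,
    )
    t0 = _stage("kinetics", t0)

    # --- GUR on the dual-echo grid; BAT segmentation; total GUR ---
    de_shape = subject.dualecho_signal.shape[:-1]
    gur_de = batseg.resample_to_grid(
        gur.data, subject.pet_affine, de_shape, subject.dualecho_affine, order=1
    )
    n_inf, n_sup = config.pet_slice_exclusion
    gur_de = batseg.exclude_slices(gur_de, n_inf, n_sup)
    gur_de_map = kinetics.GURMap(
        gur_de, _voxel_size(subject.dualecho_affine), gur.glucose_mmol_l,
        gur.lumped_constant,
    )
    bat_mask = batseg.initial_bat_mask(
        gur_de_map, config.gur_threshold, subject.removal_mask
    )
    total = batseg.total_gur(gur_de_map, bat_mask)
    t0 = _stage("batseg", t0)

    # --- multi-echo FF/R2* and mask refinement ---
    me_fit = fatwater.fit_multiecho(
        subject.multiecho_signal, subject.multiecho_tes_ms, b0_t=config.b0_t
    )
    mi, ms = config.multiecho_slice_exclusion
    rough = batseg.MaskVolume(
        batseg.exclude_slices(np.asarray(subject.rough_bat_mask) > 0, mi, ms),
        _voxel_size(subject.multiecho_affine),
        tag="initial",
    )
    refined = batseg.refine_bat_mask(
        rough, me_fit.ff, me_fit.r2s, config.ff_min, config.r2s_max
    )
    summary_me = batseg.depot_summary(
        ff=me_fit.ff, ff_mask=refined, r2s=me_fit.r2s, r2s_mask=refined
    )
    t0 = _stage("fatwater-15e", t0)

    # --- dual-echo FF; refined mask transferred; fat-mask intersection ---
    w_img, f_img = fatwater.separate_dualecho(
        subject.dualecho_signal, subject.dualecho_tes_ms, b0_t=config.b0_t
    )
    ff2 = fatwater.dualecho_ff(w_img, f_img)
    transferred = batseg.resample_to_grid(
        refined.data.astype(float), subject.multiecho_affine, de_shape,
        subject.dualecho_affine, order=0,
    ) > 0.5
    fmask = batseg.fat_mask(ff2, _voxel_size(subject.dualecho_affine), config.ff_min)
    ff2_mask = batseg.MaskVolume(
        transferred & fmask.data, _voxel_size(subject.dualecho_affine), "fat-mask"
    )
    summary_2e = batseg.depot_summary(ff=ff2, ff_mask=ff2_mask)
    t0 = _stage("fatwater-2e", t0)

    # --- thermography ---
    row = {
        "subject": subject.subject_id,
        "total_bat_gur_umol_min": total,
        "bat_ff2e_pct": summary_2e.mean_ff * 100.0,
        "bat_ff15e_pct": summary_me.mean_ff * 100.0,
        "bat_r2s_s1": summary_me.mean_r2s,
        "bat_voxel_count": bat_mask.count,
        "refined_voxel_count": refined.count,
    }
    if subject.irt_raw_frames is not None:
        temps = thermo.raw_to_temperature(subject.irt_raw_frames, subject.irt_env)
        series = thermo.ThermalSeries(temps, subject.irt_scf_mask, subject.irt_pnr_mask)
        row.update(thermo.window_means(series))
    _stage("thermo", t0)
    return row


def run_cohort(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> dict[str, pd.DataFrame | dict]:
    """Fit the 7 simple + 4 multiple regressions plus the all-pairs table.

    Returns the long-format model table, the all-pairs table, and a
    provenance manifest (row count, config, table hash).
    """
    config = config or PipelineConfig()
    n = len(table)
    max_p = max(len(s) for s in stats.MULTIPLE_PREDICTOR_SETS)
    if n < max_p + 2:
        raise ValueError(
            f"need at least {max_p + 2} subjects for the {max_p}-predictor models; got {n}"
        )
    models = stats.run_study_regressions(table)
    pairs = stats.all_pairs_regressions(
        table, [stats.RESPONSE, *stats.SIMPLE_PREDICTORS]
    )
    digest = hashlib.sha256(
        table.to_csv(index=False).encode()
    ).hexdigest()
    manifest = {
        "n_subjects": n,
        "n_models": int(models["model"].nunique()),
        "cohort_sha256": digest,
        "config": asdict(config),
    }
    return {"models": models, "pairs": pairs, "manifest": manifest}


# ---------------------------------------------------------------------------
# Synthetic subject


#: kinetic truths used for synthetic subjects: an active BAT depot, a
#: low-uptake white-fat depot, and muscle-like background uptake
_BAT_KINETICS = synthio.KineticTruth(K1=0.15, k2=0.3, k3=0.15)  # Ki = 0.05
_WAT_KINETICS = synthio.KineticTruth(K1=0.03, k2=0.5, k3=0.01)  # Ki ~ 0.00059


def make_synthetic_subject(
    seed: int = 0,
    activity_scale: float = 1.0,
    noise_level: float = 0.0,
    shape: tuple[int, int, int] = (10, 10, 16),
    config: PipelineConfig | None = None,
) -> tuple[SubjectData, SubjectTruth]:
    """Build a complete synthetic subject on a single shared grid.

    ``activity_scale`` multiplies the BAT depot's trapping rate, so cohorts
    of subjects with graded BAT activity can be generated.  All modalities
    share the grid and an identity-scaled affine; slice exclusions of the
    default config leave the central slices, where the depots live.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=int)
    zc = nz // 2
    labels[2:6, 2:6, zc - 2 : zc + 2] = 1  # BAT depot
    labels[6:9, 6:9, zc - 2 : zc + 2] = 2  # WAT depot
    labels[0:2, 6:9, :] = 3  # "aorta" column spanning all slices

    bat = synthio.KineticTruth(
        K1=_BAT_KINETICS.K1 * activity_scale,
        k2=_BAT_KINETICS.k2,
        k3=_BAT_KINETICS.k3,
    )
    schedule = kinetics.FrameSchedule.default()
    cp = synthio.make_input_function(schedule=schedule)
    spec = synthio.PhantomSpec(
        labels=labels,
        voxel_size_mm=(3.91, 3.91, 2.78),
        kinetics={1: bat, 2: _WAT_KINETICS},
        ff={1: 0.80, 2: 0.90},
        r2s={1: 44.0, 2: 31.0},
        aorta_label=3,
        noise_level=noise_level,
        seed=seed,
    )
    phantom = synthio.make_pet_phantom(spec, cp, schedule, wb_ratio=config.plasma_ratio)
    affine = np.diag([3.91, 3.91, 2.78, 1.0])

    me_tes = 1.70 + 0.65 * np.arange(15)
    me_sig = synthio.make_mr_phantom(spec, me_tes)
    de_tes = np.array([1.1, 2.2])
    de_sig = synthio.make_mr_phantom(spec, de_tes)

    glucose = 5.0
    scf_cold = 33.88 + 0.65 * rng.standard_normal()
    scf_neutral = 33.66 + 0.75 * rng.standard_normal()
    pnr_cold = 31.43 + 0.94 * rng.standard_normal()
    pnr_neutral = 32.16 + 0.56 * rng.standard_normal()
    frames = np.zeros((35, 16, 16))
    scf_mask = np.zeros((16, 16), dtype=bool)
    pnr_mask = np.zeros((16, 16), dtype=bool)
    scf_mask[10:14, 2:14] = True
    pnr_mask[2:5, 4:12] = True
    scf_t = np.concatenate(
        [np.full(5, scf_neutral), np.linspace(scf_neutral, scf_cold, 20), np.full(10, scf_cold)]
    )
    pnr_t = np.concatenate(
        [np.full(5, pnr_neutral), np.linspace(pnr_neutral, pnr_cold, 20), np.full(10, pnr_cold)]
    )
    ambient = 15.0
    frames[:] = ambient
    frames[:, scf_mask] = scf_t[:, None]
    frames[:, pnr_mask] = pnr_t[:, None]
    env = thermo.Environment(emissivity=config.emissivity)
    raw = synthio.make_irt_sequence(frames, env)

    subject = SubjectData(
        pet4d=phantom.pet4d,
        schedule=schedule,
        pet_affine=affine,
        aorta_mask=labels == 3,
        glucose_pre_mmol_l=glucose,
        glucose_post_mmol_l=glucose,
        multiecho_signal=me_sig,
        multiecho_tes_ms=me_tes,
        multiecho_affine=affine,
        rough_bat_mask=labels == 1,
        dualecho_signal=de_sig,
        dualecho_tes_ms=de_tes,
        dualecho_affine=affine,
        removal_mask=(labels == 2) | (labels == 3),  # manual-removal stand-in: non-BAT uptake and vessels
        irt_raw_frames=raw,
        irt_scf_mask=scf_mask,
        irt_pnr_mask=pnr_mask,
        irt_env=env,
        subject_id=seed,
    )
    truth = SubjectTruth(
        total_bat_gur_umol_min=synthio.total_gur_truth(spec, glucose, include={1}),
        ki={lab: t.ki for lab, t in spec.kinetics.items()},
        ff=dict(spec.ff),
        r2s=dict(spec.r2s),
        scf_neutral_c=scf_neutral,
        scf_cold_c=scf_cold,
        pnr_neutral_c=pnr_neutral,
        pnr_cold_c=pnr_cold,
    )
    return subject, truth
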