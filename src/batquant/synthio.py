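"""Synthetic ground-truth generators for every pipeline stage.

Provides plasma input curves (Feng-type tri-exponential with a linear
upslope), forward-simulated irreversible two-tissue tissue curves, 4-D PET
phantoms with an aorta label, multi-/dual-echo gradient-echo MR phantoms with
a multi-peak fat spectrum, raw radiometric infrared frame sequences built by
inverting the camera compensation model, and small regression cohorts with a
known linear effect structure.  Every generator is seeded and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import (
    DEFAULT_FINE_STEP_S,
    FrameSchedule,
    InputFunction,
    TimeActivityCurve,
    conv_exp,
    frame_average,
)
from scipy.integrate import cumulative_trapezoid

from . import thermo as _thermo
from .fatwater import DEFAULT_SPECTRUM, FatSpectrum

__all__ = [
    "KineticTruth",
    "FengParams",
    "PhantomSpec",
    "CohortSpec",
    "make_input_function",
    "simulate_tac",
    "make_pet_phantom",
    "make_mr_phantom",
    "make_irt_sequence",
    "make_cohort",
    "TABLE1_PREDICTORS",
]


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth rate constants of the irreversible two-tissue model."""

    K1: float  # ml/ml/min
    k2: float  # 1/min
    k3: float  # 1/min
    vb: float = 0.0  # blood volume fraction

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be non-negative")
        if self.K1 > 0 and self.k2 + self.k3 == 0:
            raise ValueError("k2 + k3 must be positive when K1 > 0")
        if not 0 <= self.vb < 1:
            raise ValueError("vb must be in [0, 1)")

    @property
    def ki(self) -> float:
        """Net influx rate K1*k3/(k2+k3); 0 when there is no influx."""
        if self.K1 == 0:
            return 0.0
        return self.K1 * self.k3 / (self.k2 + self.k3)

    @property
    def theta(self) -> float:
        return self.k2 + self.k3


@dataclass(frozen=True)
class FengParams:
    """Feng-type arterial input model: linear upslope times an exponential
    plus two slower exponentials, all delayed by ``t0``.

    Cp(t) = (a1*(t-t0) - a2 - a3) * exp(-l1*(t-t0))
            + a2 * exp(-l2*(t-t0)) + a3 * exp(-l3*(t-t0))   for t >= t0.

    Defaults are arbitrary but FDG-plausible (kBq/ml, minutes).
    """

    a1: float = 851.1
    a2: float = 21.9
    a3: float = 20.8
    l1: float = 4.134
    l2: float = 0.119
    l3: float = 0.0104
    t0: float = 0.4

    def __post_init__(self) -> None:
        vals = [self.a1, self.a2, self.a3, self.l1, self.l2, self.l3, self.t0]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("non-finite input-function parameters")
        if min(self.l1, self.l2, self.l3) <= 0:
            raise ValueError("decay rates must be positive")

    def evaluate(self, t_min: np.ndarray) -> np.ndarray:
        tau = np.asarray(t_min, dtype=float) - self.t0
        out = np.where(
            tau >= 0,
            (self.a1 * tau - self.a2 - self.a3) * np.exp(-self.l1 * np.maximum(tau, 0))
            + self.a2 * np.exp(-self.l2 * np.maximum(tau, 0))
            + self.a3 * np.exp(-self.l3 * np.maximum(tau, 0)),
            0.0,
        )
        return np.clip(out, 0.0, None)


def make_input_function(
    params: FengParams | None = None,
    schedule: FrameSchedule | None = None,
    step_s: float = DEFAULT_FINE_STEP_S,
) -> InputFunction:
    """Evaluate the Feng model on the schedule's fine grid."""
    params = params or FengParams()
    schedule = schedule or FrameSchedule.default()
    t = schedule.fine_times_min(step_s)
    return InputFunction(t, params.evaluate(t))


def simulate_tac(
    truth: KineticTruth,
    cp: InputFunction,
    schedule: FrameSchedule,
    blood: InputFunction | None = None,
) -> TimeActivityCurve:
    """Forward-simulate a frame-averaged tissue curve of the irreversible
    two-tissue model:

        C_T = Ki * int Cp + [K1*k2/(k2+k3)] * (Cp (*) exp(-(k2+k3) t)) + vb*C_b
    """
    if not cp.covers(schedule):
        raise ValueError("input function does not cover the schedule")
    t = cp.times_min
    if truth.K1 == 0:
        fine = np.zeros_like(t)
    else:
        theta = truth.theta
        irr = cumulative_trapezoid(cp.plasma, t, initial=0.0)
        fine = truth.ki * irr
        amp = truth.K1 * truth.k2 / theta
        if amp > 0:
            fine = fine + amp * conv_exp(cp.plasma, t, theta)
    if truth.vb > 0:
        cb = blood.plasma if blood is not None else cp.plasma
        fine = fine + truth.vb * cb
    return TimeActivityCurve(schedule, frame_average(fine, t, schedule))


# ---------------------------------------------------------------------------
# PET phantom


@dataclass
class PhantomSpec:
    """Geometry, per-label ground truth and noise level of a phantom.

    ``labels`` is an integer volume; label 0 is background.  ``kinetics``
    maps label -> KineticTruth, ``ff`` and ``r2s`` map label -> fat fraction
    (0..1) and R2* (1/s).  ``noise_level`` is the noise standard deviation as
    a fraction of the peak noiseless signal.
    """

    labels: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.91, 3.91, 2.78)
    kinetics: dict[int, KineticTruth] = field(default_factory=dict)
    ff: dict[int, float] = field(default_factory=dict)
    r2s: dict[int, float] = field(default_factory=dict)
    aorta_label: int | None = None
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        for v in self.ff.values():
            if not 0 <= v <= 1:
                raise ValueError("fat-fraction truth must be in [0, 1]")
        for v in self.r2s.values():
            if v < 0:
                raise ValueError("R2* truth must be non-negative")
        if self.noise_level < 0:
            raise ValueError("noise level must be non-negative")


@dataclass
class PetPhantom:
    """A simulated dynamic PET acquisition with its ground truth."""

    pet4d: np.ndarray
    labels: np.ndarray
    schedule: FrameSchedule
    spec: PhantomSpec
    label_tacs: dict[int, np.ndarray]
    ki_truth: dict[int, float]

    def write(self, directory) -> None:
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aff = np.diag(list(self.spec.voxel_size_mm) + [1.0])
        nib.save(nib.Nifti1Image(self.pet4d.astype(np.float32), aff),
                 directory / "pet4d.nii.gz")
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff),
                 directory / "labels.nii.gz")
        self.schedule.to_csv(directory / "schedule.csv")
        truth = {
            "ki": {str(k): v for k, v in self.ki_truth.items()},
            "voxel_size_mm": list(self.spec.voxel_size_mm),
            "noise_level": self.spec.noise_level,
            "seed": self.spec.seed,
        }
        (directory / "truth.json").write_text(json.dumps(truth, indent=2))


def make_pet_phantom(
    spec: PhantomSpec,
    cp: InputFunction,
    schedule: FrameSchedule | None = None,
    wb_ratio: float = 1.1,
) -> PetPhantom:
    """Build a 4-D PET volume from per-label simulated tissue curves.

    Each labelled voxel carries its label's noiseless tissue curve plus
    seeded Gaussian noise whose variance scales inversely with frame
    duration.  The aorta label (if any) carries the whole-blood curve, i.e.
    the plasma curve divided by the plasma-to-whole-blood ratio.
    """
    schedule = schedule or FrameSchedule.default()
    labels = spec.labels
    rng = np.random.default_rng(spec.seed)
    label_tacs: dict[int, np.ndarray] = {}
    ki_truth: dict[int, float] = {}
    for lab, truth in spec.kinetics.items():
        label_tacs[lab] = simulate_tac(truth, cp, schedule).activity
        ki_truth[lab] = truth.ki
    if spec.aorta_label is not None:
        wb_fine = cp.plasma / wb_ratio
        label_tacs[spec.aorta_label] = frame_average(wb_fine, cp.times_min, schedule)

    pet4d = np.zeros(labels.shape + (schedule.n_frames,))
    for lab, tac in label_tacs.items():
        pet4d[labels == lab] = tac
    if spec.noise_level > 0:
        peak = max(float(np.abs(pet4d).max()), 1e-12)
        # variance ~ 1/duration, normalised to the mean frame duration
        sd = spec.noise_level * peak * np.sqrt(
            schedule.durations_s.mean() / schedule.durations_s
        )
        pet4d = pet4d + rng.standard_normal(pet4d.shape) * sd
    return PetPhantom(pet4d, labels, schedule, spec, label_tacs, ki_truth)


def total_gur_truth(
    spec: PhantomSpec, glucose_mmol_l: float, include: set[int] | None = None
) -> float:
    """Analytic total GUR (umol/min) of the labelled depots:
    sum over voxels of Ki * glucose * voxel volume (ml) / ... expressed via
    GUR = Ki*glucose*100 umol/100ml/min, total = sum GUR * vox_ml / 100."""
    vox_ml = float(np.prod(spec.voxel_size_mm)) / 1000.0
    total = 0.0
    for lab, truth in spec.kinetics.items():
        if include is not None and lab not in include:
            continue
        n = int(np.sum(spec.labels == lab))
        total += truth.ki * glucose_mmol_l * 100.0 * n * vox_ml / 100.0
    return total


# ---------------------------------------------------------------------------
# MR phantom


def fat_water_signal(
    ff: float | np.ndarray,
    r2s: float | np.ndarray,
    tes_ms: np.ndarray,
    amplitude: float | np.ndarray = 100.0,
    spectrum: FatSpectrum = DEFAULT_SPECTRUM,
    b0_t: float = 3.0,
) -> np.ndarray:
    """Complex gradient-echo signal of a water/fat voxel:

        S(TE) = A * ((1-FF) + FF * c(TE)) * exp(-R2* * TE)

    with ``c(TE)`` the complex multi-peak fat spectrum phasor; TEs in ms."""
    tes_ms = np.asarray(tes_ms, dtype=float)
    if np.any(tes_ms < 0):
        raise ValueError("echo times must be non-negative")
    c = spectrum.phasor(tes_ms, b0_t)  # (n_echo,)
    ff = np.asarray(ff, dtype=float)[..., None]
    r2s = np.asarray(r2s, dtype=float)[..., None]
    amp = np.asarray(amplitude, dtype=float)[..., None]
    decay = np.exp(-r2s * tes_ms * 1e-3)
    return amp * ((1.0 - ff) + ff * c) * decay


def make_mr_phantom(
    spec: PhantomSpec,
    tes_ms: np.ndarray,
    amplitude: float = 100.0,
    spectrum: FatSpectrum = DEFAULT_SPECTRUM,
    b0_t: float = 3.0,
) -> np.ndarray:
    """Per-voxel complex echo stack (x, y, z, n_echo) from the label truths."""
    tes_ms = np.asarray(tes_ms, dtype=float)
    if tes_ms.size < 2:
        raise ValueError("need at least two echoes")
    ff_vol = np.zeros(spec.labels.shape)
    r2s_vol = np.zeros(spec.labels.shape)
    amp_vol = np.zeros(spec.labels.shape)
    for lab, ff in spec.ff.items():
        ff_vol[spec.labels == lab] = ff
        amp_vol[spec.labels == lab] = amplitude
    for lab, r in spec.r2s.items():
        r2s_vol[spec.labels == lab] = r
    sig = fat_water_signal(ff_vol, r2s_vol, tes_ms, amp_vol, spectrum, b0_t)
    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed + 1)
        sd = spec.noise_level * max(float(np.abs(sig).max()), 1e-12)
        sig = sig + sd * (
            rng.standard_normal(sig.shape) + 1j * rng.standard_normal(sig.shape)
        ) / np.sqrt(2.0)
    return sig


# ---------------------------------------------------------------------------
# Infrared thermography


def make_irt_sequence(
    temps_c: np.ndarray,
    env: "_thermo.Environment",
    pc: "_thermo.PlanckConstants | None" = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Raw radiometric frames whose compensated temperature equals ``temps_c``.

    Inverts the object-temperature equation of :func:`thermo.raw_to_temperature`:
    raw = eps*tau*S(T) + (1-eps)*tau*S(T_refl) + (1-tau)*S(T_atm).
    """
    pc = pc or _thermo.PlanckConstants()
    temps_c = np.asarray(temps_c, dtype=float)
    if np.any(temps_c < -273.15):
        raise ValueError("temperatures below 0 K")
    tau = _thermo.atmospheric_transmission(env)
    s_obj = _thermo.temperature_to_signal(temps_c, pc)
    s_refl = _thermo.temperature_to_signal(env.reflected_temperature_c, pc)
    s_atm = _thermo.temperature_to_signal(env.atmospheric_temperature_c, pc)
    raw = env.emissivity * tau * s_obj + (1 - env.emissivity) * tau * s_refl + (
        1 - tau
    ) * s_atm
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.standard_normal(raw.shape) * noise_sd
    return raw


# ---------------------------------------------------------------------------
# Regression cohorts

#: Cohort-level predictor means and standard deviations used as generator
#: defaults (temperatures in deg C, fat fractions in percent, R2* in 1/s).
TABLE1_PREDICTORS: dict[str, tuple[float, float]] = {
    "scf_neutral_c": (33.66, 0.75),
    "scf_cold_c": (33.88, 0.65),
    "pnr_neutral_c": (32.16, 0.56),
    "pnr_cold_c": (31.43, 0.94),
    "bat_ff2e_pct": (83.3, 5.5),
    "bat_ff15e_pct": (79.8, 7.1),
    "bat_r2s_s1": (44.0, 11.0),
}

RESPONSE_COLUMN = "total_bat_gur_umol_min"


@dataclass
class CohortSpec:
    """Linear effect structure of a synthetic cohort.

    The default is the cold supraclavicular skin temperature driving total
    BAT glucose uptake with slope 48.07 umol/min per deg C and intercept
    -1591 umol/min; the residual standard deviation (27.5 umol/min) is chosen
    so that the simple regression explains about half the response variance
    at the default predictor spread.
    """

    n: int = 12
    coefficients: dict[str, float] = field(
        default_factory=lambda: {"scf_cold_c": 48.07}
    )
    intercept: float = -1591.0
    residual_sd: float = 27.5
    predictor_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE1_PREDICTORS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < len(self.coefficients) + 2:
            raise ValueError("n must be at least number of predictors + 2")
        if self.residual_sd < 0:
            raise ValueError("residual sd must be non-negative")
        missing = set(self.coefficients) - set(self.predictor_moments)
        if missing:
            raise ValueError(f"no moments for predictors: {sorted(missing)}")
        for name, (_, sd) in self.predictor_moments.items():
            if sd < 0:
                raise ValueError(f"negative sd for {name}")
        drivers = [p for p in self.coefficients if self.coefficients[p] != 0]
        if drivers and all(self.predictor_moments[p][1] == 0 for p in drivers):
            raise ValueError("singular predictor covariance: all drivers constant")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a per-subject measurement table with a known linear response.

    Predictors are drawn independently from the stated means/sds; the
    response is the linear combination plus Gaussian noise.  The ground-truth
    coefficients are attached as ``df.attrs['truth']``.
    """
    rng = np.random.default_rng(spec.seed)
    data: dict[str, np.ndarray] = {}
    for name, (mean, sd) in spec.predictor_moments.items():
        data[name] = mean + sd * rng.standard_normal(spec.n)
    y = np.full(spec.n, spec.intercept, dtype=float)
    for name, beta in spec.coefficients.items():
        y = y + beta * data[name]
    y = y + spec.residual_sd * rng.standard_normal(spec.n)
    df = pd.DataFrame({RESPONSE_COLUMN: y, **data})
    df.insert(0, "subject", np.arange(1, spec.n + 1))
    df.attrs["truth"] = {
        "coefficients": dict(spec.coefficients),
        "intercept": spec.intercept,
        "residual_sd": spec.residual_sd,
    }
    return df
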