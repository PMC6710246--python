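"""Dynamic FDG-PET kinetics: image-derived input function and basis-function
fitting of the irreversible two-tissue compartment model.

The net influx (trapping) rate is ``Ki = K1*k3/(k2+k3)``.  The tissue curve of
the irreversible model can be written as

    C_T(t) = Ki * int_0^t Cp(s) ds  +  A * (Cp (*) exp(-theta*t))(t)

with ``theta = k2 + k3`` and ``A = K1*k2/(k2+k3)``.  The basis-function method
precomputes the convolution term on a logarithmic grid of clearance rates
``theta`` and, for each grid value, solves a two-parameter non-negative linear
least-squares problem per voxel; the grid value with the smallest weighted
residual wins.  Glucose uptake rate maps are ``Ki`` scaled by the mean serum
glucose (lumped constant 1), in umol/100 ml/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "InputFunction",
    "BasisSet",
    "KineticFit",
    "GURMap",
    "extract_idif",
    "blood_to_plasma",
    "build_basis",
    "fit_voxel",
    "fit_voxels",
    "ki_map",
    "gur_map",
]

#: (count, duration_s) blocks of the default 45-minute dynamic acquisition.
DEFAULT_FRAME_BLOCKS: tuple[tuple[int, float], ...] = (
    (1, 10),
    (8, 5),
    (4, 10),
    (2, 15),
    (3, 20),
    (2, 30),
    (6, 60),
    (4, 150),
    (5, 300),
)

#: Fine-grid step used for convolutions and resampling, in seconds.
DEFAULT_FINE_STEP_S = 0.5


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (seconds) of a dynamic PET acquisition."""

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)
        if starts.ndim != 1 or starts.shape != durs.shape:
            raise ValueError("starts and durations must be 1-D and equal length")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        ends = starts + durs
        if np.any(ends[:-1] > starts[1:] + 1e-9):
            raise ValueError("frames must not overlap")

    @classmethod
    def from_blocks(cls, blocks=DEFAULT_FRAME_BLOCKS) -> "FrameSchedule":
        durs = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @classmethod
    def default(cls) -> "FrameSchedule":
        return cls.from_blocks()

    @property
    def n_frames(self) -> int:
        return self.starts_s.size

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def midpoints_min(self) -> np.ndarray:
        return self.midpoints_s / 60.0

    @property
    def total_s(self) -> float:
        return float(self.ends_s[-1])

    def fine_times_min(self, step_s: float = DEFAULT_FINE_STEP_S) -> np.ndarray:
        """Uniform fine grid (minutes) from 0 to the end of the last frame."""
        n = int(round(self.total_s / step_s)) + 1
        return np.arange(n) * (step_s / 60.0)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "start_s": self.starts_s,
                "duration_s": self.durations_s,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FrameSchedule":
        df = pd.read_csv(path).sort_values("frame_index")
        return cls(df["start_s"].to_numpy(), df["duration_s"].to_numpy())


@dataclass
class TimeActivityCurve:
    """Per-frame activity concentration (kBq/ml) on a frame schedule."""

    schedule: FrameSchedule
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ValueError("activity length must match schedule")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite")


@dataclass
class InputFunction:
    """Plasma activity on a uniform fine grid (times in minutes)."""

    times_min: np.ndarray
    plasma: np.ndarray
    whole_blood: TimeActivityCurve | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.plasma = np.asarray(self.plasma, dtype=float)
        if self.times_min.shape != self.plasma.shape:
            raise ValueError("times and plasma must have equal shapes")
        steps = np.diff(self.times_min)
        if steps.size and (np.ptp(steps) > 1e-9 or steps[0] > 1.0 / 60.0 + 1e-12):
            raise ValueError("fine grid must be uniform with step <= 1 s")
        if np.any(self.plasma < -1e-12):
            raise ValueError("plasma activity must be non-negative")

    @property
    def step_min(self) -> float:
        return float(self.times_min[1] - self.times_min[0])

    def covers(self, schedule: FrameSchedule) -> bool:
        return self.times_min[-1] * 60.0 >= schedule.total_s - 1e-6


@dataclass
class BasisSet:
    """Frame-averaged basis curves for the irreversible two-tissue model.

    ``basis[:, j]`` is the convolution of the plasma curve with
    ``exp(-thetas[j] * t)`` averaged over each frame; ``irr_basis`` is the
    frame-averaged running integral of the plasma curve.
    """

    schedule: FrameSchedule
    thetas: np.ndarray
    basis: np.ndarray
    irr_basis: np.ndarray
    cp: InputFunction


@dataclass
class KineticFit:
    """Result of a single-voxel basis-function fit."""

    ki: float
    amplitude: float
    theta: float
    rss: float
    rss_ki_only: float
    weights: np.ndarray


@dataclass
class GURMap:
    """Glucose uptake rate volume in umol/100 ml/min."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    glucose_mmol_l: float
    lumped_constant: float = 1.0

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


# ---------------------------------------------------------------------------
# Fine-grid numerics


def frame_average(values: np.ndarray, times_min: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame (integral / duration)."""
    cum = cumulative_trapezoid(values, times_min, initial=0.0)
    starts = schedule.starts_s / 60.0
    ends = schedule.ends_s / 60.0
    c_start = np.interp(starts, times_min, cum)
    c_end = np.interp(ends, times_min, cum)
    return (c_end - c_start) / (ends - starts)


def conv_exp(values: np.ndarray, times_min: np.ndarray, theta: float) -> np.ndarray:
    """Trapezoidal convolution of a fine-grid curve with ``exp(-theta*t)``."""
    dt = times_min[1] - times_min[0]
    kernel = np.exp(-theta * times_min)
    full = np.convolve(values, kernel)[: values.size]
    # trapezoid endpoint correction for the discrete convolution sum
    return dt * (full - 0.5 * (values[0] * kernel + values * kernel[0]))


# ---------------------------------------------------------------------------
# Input function


def extract_idif(
    pet4d: np.ndarray,
    aorta_mask: np.ndarray,
    schedule: FrameSchedule,
    excluded_inferior_slices: int = 0,
) -> TimeActivityCurve:
    """Mean whole-blood activity per frame over an aortic ROI.

    The ``excluded_inferior_slices`` lowest slices along the third voxel axis
    are dropped from the mask before averaging (they are typically of poor
    image quality at the edge of the axial field of view).
    """
    pet4d = np.asarray(pet4d, dtype=float)
    mask = np.asarray(aorta_mask) > 0
    if pet4d.shape[:3] != mask.shape:
        raise ValueError("mask shape must match the spatial PET shape")
    if pet4d.shape[3] != schedule.n_frames:
        raise ValueError("PET frame count must match the schedule")
    retained = mask.copy()
    if excluded_inferior_slices:
        retained[:, :, :excluded_inferior_slices] = False
    if not retained.any():
        raise ValueError(
            f"aorta mask empty after excluding {excluded_inferior_slices} inferior slices"
        )
    tac = pet4d[retained].mean(axis=0)
    return TimeActivityCurve(schedule, tac)


def blood_to_plasma(
    wb: TimeActivityCurve,
    ratio: float = 1.1,
    step_s: float = DEFAULT_FINE_STEP_S,
) -> InputFunction:
    """Convert a whole-blood curve to a plasma input function.

    Plasma activity is ``ratio`` times whole blood.  Frame values are placed
    at frame midpoints and linearly interpolated onto the fine grid; the curve
    is anchored at zero at t=0 so that it stays at zero before the first
    midpoint's rise.
    """
    if not ratio > 0:
        raise ValueError("plasma-to-whole-blood ratio must be positive")
    t = wb.schedule.fine_times_min(step_s)
    mids = wb.schedule.midpoints_min
    vals = ratio * wb.activity
    xs, ys = mids, vals
    if mids[0] > 0:
        xs = np.concatenate([[0.0], mids])
        ys = np.concatenate([[0.0], vals])
    plasma = np.interp(t, xs, ys)
    return InputFunction(t, np.clip(plasma, 0.0, None), whole_blood=wb)


# ---------------------------------------------------------------------------
# Basis functions and fitting


def build_basis(
    cp: InputFunction,
    schedule: FrameSchedule,
    n: int = 50,
    theta_min: float = 0.02,
    theta_max: float = 1.0,
) -> BasisSet:
    """Precompute the clearance-rate basis for the basis-function method.

    ``n`` log-spaced clearance rates between ``theta_min`` and ``theta_max``
    (1/min) plus one irreversible basis (running integral of the plasma
    curve); every basis curve is frame-averaged.
    """
    if not (theta_min > 0 and theta_max > theta_min and n >= 2):
        raise ValueError("need theta_max > theta_min > 0 and n >= 2")
    if not cp.covers(schedule):
        raise ValueError("input function does not cover the frame schedule")
    thetas = np.geomspace(theta_min, theta_max, n)
    t = cp.times_min
    irr_fine = cumulative_trapezoid(cp.plasma, t, initial=0.0)
    irr = frame_average(irr_fine, t, schedule)
    basis = np.empty((schedule.n_frames, n))
    for j, theta in enumerate(thetas):
        basis[:, j] = frame_average(conv_exp(cp.plasma, t, theta), t, schedule)
    basis = np.clip(basis, 0.0, None)
    return BasisSet(schedule, thetas, basis, np.clip(irr, 0.0, None), cp)


def _nnls2(
    g11: float, g12: np.ndarray, g22: np.ndarray, c1: np.ndarray, c2: np.ndarray
):
    """Vectorised 2-variable non-negative least squares via KKT enumeration.

    Minimises ``|y - a*b1 - b*b2|_W^2`` over a,b >= 0 given the Gram entries
    ``g11=<b1,b1>, g12=<b1,b2>, g22=<b2,b2>`` and cross products
    ``c1=<y,b1>, c2=<y,b2>``.  Returns (a, b, fit_reduction) where the RSS is
    ``<y,y> - fit_reduction``.
    """
    det = g11 * g22 - g12**2
    with np.errstate(divide="ignore", invalid="ignore"):
        a_int = (g22 * c1 - g12 * c2) / det
        b_int = (g11 * c2 - g12 * c1) / det
        red_int = a_int * c1 + b_int * c2
        a_only = np.maximum(c1 / g11, 0.0) if g11 > 0 else np.zeros_like(c1)
        b_only = np.where(g22 > 0, np.maximum(c2 / g22, 0.0), 0.0)
    red_a = a_only * c1
    red_b = b_only * c2
    interior_ok = (det > 0) & (a_int >= 0) & (b_int >= 0) & np.isfinite(red_int)
    # best feasible candidate: interior if admissible, else best axis fit, else 0
    use_a = red_a >= red_b
    a = np.where(interior_ok, a_int, np.where(use_a, a_only, 0.0))
    b = np.where(interior_ok, b_int, np.where(use_a, 0.0, b_only))
    red = np.where(interior_ok, red_int, np.maximum(red_a, red_b))
    return a, b, np.maximum(red, 0.0)


def fit_voxels(
    tacs: np.ndarray,
    basis: BasisSet,
    weights: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Basis-function fit of many TACs at once.

    ``tacs`` has shape (n_voxels, n_frames).  For every clearance rate on the
    grid a weighted two-parameter non-negative fit ``C_T ~ Ki*B_irr + A*B_th``
    is solved in closed form; the grid value with the smallest weighted RSS is
    kept (ties go to the smaller clearance rate).  Weights default to frame
    durations.
    """
    tacs = np.atleast_2d(np.asarray(tacs, dtype=float))
    sched = basis.schedule
    if tacs.shape[1] != sched.n_frames:
        raise ValueError("TAC length must match the basis schedule")
    if not np.all(np.isfinite(tacs)):
        raise ValueError("non-finite TAC values")
    if weights is None:
        weights = sched.durations_s.copy()
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be non-negative with at least one positive")

    b1 = basis.irr_basis
    if not np.any(b1 > 0) and not np.any(basis.basis > 0):
        raise ValueError("all-zero basis")
    yw = tacs * w  # (nv, nf)
    yty = np.einsum("ij,ij->i", yw, tacs)
    g11 = float(np.sum(w * b1 * b1))
    c1 = yw @ b1

    n_theta = basis.thetas.size
    best_red = np.full(tacs.shape[0], -np.inf)
    best = {
        "ki": np.zeros(tacs.shape[0]),
        "amplitude": np.zeros(tacs.shape[0]),
        "theta": np.full(tacs.shape[0], basis.thetas[0]),
    }
    for j in range(n_theta):
        b2 = basis.basis[:, j]
        g12 = float(np.sum(w * b1 * b2))
        g22 = float(np.sum(w * b2 * b2))
        a, b, red = _nnls2(g11, np.full(1, g12), np.full(1, g22), c1, yw @ b2)
        better = red > best_red + 1e-12  # strict: ties keep the smaller theta
        best_red = np.where(better, red, best_red)
        best["ki"] = np.where(better, a, best["ki"])
        best["amplitude"] = np.where(better, b, best["amplitude"])
        best["theta"] = np.where(better, basis.thetas[j], best["theta"])

    # Ki-only (pure trapping, Patlak-style) reference fit
    ki_only = np.maximum(c1 / g11, 0.0) if g11 > 0 else np.zeros_like(c1)
    rss_ki_only = np.maximum(yty - ki_only * c1, 0.0)
    rss = np.maximum(yty - np.maximum(best_red, 0.0), 0.0)
    best["rss"] = np.minimum(rss, rss_ki_only)
    best["rss_ki_only"] = rss_ki_only
    return best


def fit_voxel(
    tac: TimeActivityCurve,
    basis: BasisSet,
    weights: np.ndarray | None = None,
) -> KineticFit:
    """Fit one time-activity curve; see :func:`fit_voxels`."""
    if tac.schedule.n_frames != basis.schedule.n_frames:
        raise ValueError("TAC and basis must share the schedule")
    if weights is None:
        weights = basis.schedule.durations_s.copy()
    res = fit_voxels(tac.activity[None, :], basis, weights)
    return KineticFit(
        ki=float(res["ki"][0]),
        amplitude=float(res["amplitude"][0]),
        theta=float(res["theta"][0]),
        rss=float(res["rss"][0]),
        rss_ki_only=float(res["rss_ki_only"][0]),
        weights=np.asarray(weights, dtype=float),
    )


def ki_map(
    pet4d: np.ndarray,
    basis: BasisSet,
    body_mask: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Voxelwise net-influx-rate map; voxels outside the mask are zero."""
    pet4d = np.asarray(pet4d, dtype=float)
    shape = pet4d.shape[:3]
    if body_mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(body_mask) > 0
        if mask.shape != shape:
            raise ValueError("body mask shape must match the PET spatial shape")
    out = np.zeros(shape)
    if mask.any():
        res = fit_voxels(pet4d[mask], basis, weights)
        out[mask] = res["ki"]
    return out


def gur_map(
    ki: np.ndarray,
    glucose_pre_mmol_l: float,
    glucose_post_mmol_l: float,
    voxel_size_mm: tuple[float, float, float],
    lumped_constant: float = 1.0,
) -> GURMap:
    """Scale a Ki map by mean serum glucose to umol/100 ml/min.

    With glucose in mmol/l (== umol/ml) and Ki in ml/ml/min, GUR per 100 ml of
    tissue is ``Ki * glucose * 100 / LC``.
    """
    if not (glucose_pre_mmol_l > 0 and glucose_post_mmol_l > 0):
        raise ValueError("serum glucose values must be positive")
    if not lumped_constant > 0:
        raise ValueError("lumped constant must be positive")
    glc = 0.5 * (glucose_pre_mmol_l + glucose_post_mmol_l)
    data = np.asarray(ki, dtype=float) * glc * 100.0 / lumped_constant
    return GURMap(data=data, voxel_size_mm=tuple(voxel_size_mm), glucose_mmol_l=glc,
                  lumped_constant=lumped_constant)
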