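"""Water-fat separation and R2* mapping from gradient-echo MRI.

Two estimators are provided:

* :func:`fit_multiecho` — magnitude-domain nonlinear least squares of the
  multi-peak single-R2* signal model on a multi-echo train, with multi-start
  initialisation to resolve the water/fat dominance ambiguity;
* :func:`separate_dualecho` — a two-point complex separation at two echo
  times that neglects R2* decay and B0 field offset, plus the elementary
  fat-fraction map ``F/(W+F)`` from pre-separated water/fat images.

Fat fractions are proton-density style fractions in [0, 1]; R2* is in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FatSpectrum",
    "DEFAULT_SPECTRUM",
    "FatWaterFit",
    "fit_multiecho",
    "separate_dualecho",
    "dualecho_ff",
]

GYROMAGNETIC_MHZ_PER_T = 42.577


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat spectrum: chemical shifts (ppm, relative to water,
    negative = lower frequency) and relative amplitudes summing to 1."""

    shifts_ppm: tuple[float, ...]
    amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.shifts_ppm) != len(self.amplitudes):
            raise ValueError("shifts and amplitudes must have equal length")
        total = sum(self.amplitudes)
        if not total > 0:
            raise ValueError("amplitudes must have a positive sum")
        # published relative amplitudes often sum to ~0.999; normalise exactly
        object.__setattr__(
            self, "amplitudes", tuple(a / total for a in self.amplitudes)
        )

    def phasor(self, tes_ms: np.ndarray, b0_t: float = 3.0) -> np.ndarray:
        """Complex fat signal per unit fat at each echo time."""
        tes_s = np.asarray(tes_ms, dtype=float) * 1e-3
        freqs_hz = np.array(self.shifts_ppm) * GYROMAGNETIC_MHZ_PER_T * b0_t  # ppm*MHz = Hz
        amps = np.array(self.amplitudes)
        return (amps[:, None] * np.exp(2j * np.pi * freqs_hz[:, None] * tes_s)).sum(axis=0)


#: Six-peak triglyceride spectrum (methyl through olefinic protons).
DEFAULT_SPECTRUM = FatSpectrum(
    shifts_ppm=(-3.80, -3.40, -2.60, -1.94, -0.39, 0.60),
    amplitudes=(0.087, 0.693, 0.128, 0.004, 0.039, 0.048),
)


@dataclass
class FatWaterFit:
    """Per-voxel water/fat amplitudes, fat fraction, R2* and residual.

    Arrays share the spatial shape of the input; voxels that could not be
    fitted (zero signal) carry NaN in ``ff`` and ``r2s``.
    """

    water: np.ndarray
    fat: np.ndarray
    ff: np.ndarray
    r2s: np.ndarray
    rss: np.ndarray


R2S_BOUNDS = (0.0, 500.0)


def _magnitude_model(params, tes_s, phasor):
    m, ff, r2s = params
    return m * np.abs((1.0 - ff) + ff * phasor) * np.exp(-r2s * tes_s)


def _fit_one(mag: np.ndarray, tes_s: np.ndarray, phasor: np.ndarray):
    """Multi-start bounded least squares of (M, FF, R2*) on one voxel."""
    scale = float(mag.max())
    best = None
    for ff0 in (0.1, 0.9):
        for r2s0 in (0.0, 100.0):
            res = least_squares(
                lambda p: _magnitude_model(p, tes_s, phasor) - mag,
                x0=[scale, ff0, r2s0],
                bounds=([0.0, 0.0, R2S_BOUNDS[0]], [np.inf, 1.0, R2S_BOUNDS[1]]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            rss = float(2 * res.cost)
            # ties resolved toward the lower R2* solution
            if best is None or rss < best[1] - 1e-12 * (1 + best[1]) or (
                abs(rss - best[1]) <= 1e-12 * (1 + best[1]) and res.x[2] < best[0][2]
            ):
                best = (res.x, rss)
    return best


def fit_multiecho(
    signal: np.ndarray,
    tes_ms: np.ndarray,
    spectrum: FatSpectrum = DEFAULT_SPECTRUM,
    b0_t: float = 3.0,
    signal_floor: float = 1e-6,
) -> FatWaterFit:
    """Voxelwise magnitude fit of ``|S(TE)| = M*|(1-FF) + FF*c(TE)|*e^(-R2* TE)``.

    ``signal`` is a (..., n_echo) stack, complex or magnitude.  Voxels whose
    peak magnitude falls below ``signal_floor`` times the volume maximum are
    flagged undefined (NaN) instead of fitted.
    """
    tes_ms = np.asarray(tes_ms, dtype=float)
    if tes_ms.size < 3:
        raise ValueError("need at least 3 echoes for the 3-parameter fit")
    if np.any(np.diff(tes_ms) <= 0):
        raise ValueError("echo times must be strictly increasing")
    mag = np.abs(np.asarray(signal))
    shape = mag.shape[:-1]
    flat = mag.reshape(-1, tes_ms.size)
    tes_s = tes_ms * 1e-3
    phasor = spectrum.phasor(tes_ms, b0_t)

    n = flat.shape[0]
    water = np.zeros(n)
    fat = np.zeros(n)
    ff = np.full(n, np.nan)
    r2s = np.full(n, np.nan)
    rss = np.zeros(n)
    floor = signal_floor * max(float(flat.max()), 0.0)
    for i in range(n):
        peak = flat[i].max()
        if peak <= max(floor, 0.0) or peak == 0.0:
            continue  # undefined voxel
        (m, f, r), cost = _fit_one(flat[i], tes_s, phasor)
        water[i] = m * (1 - f)
        fat[i] = m * f
        ff[i] = f
        r2s[i] = r
        rss[i] = cost
    return FatWaterFit(
        water.reshape(shape),
        fat.reshape(shape),
        ff.reshape(shape),
        r2s.reshape(shape),
        rss.reshape(shape),
    )


def separate_dualecho(
    signal: np.ndarray,
    tes_ms: np.ndarray,
    spectrum: FatSpectrum = DEFAULT_SPECTRUM,
    b0_t: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-point water/fat separation from complex dual-echo data.

    Solves per voxel the linear system ``S(TE_j) = W + F*c(TE_j)`` assuming
    zero field offset and neglecting R2* decay; returns magnitude water and
    fat images.  The neglect of R2* biases the result slightly at high R2*.
    """
    tes_ms = np.asarray(tes_ms, dtype=float)
    if tes_ms.size != 2:
        raise ValueError("dual-echo separation needs exactly 2 echoes")
    sig = np.asarray(signal)
    if sig.shape[-1] != 2:
        raise ValueError("signal must have 2 echoes in the last axis")
    c1, c2 = spectrum.phasor(tes_ms, b0_t)
    det = c2 - c1
    if abs(det) < 1e-9:
        raise ValueError("singular two-point system: fat phasors coincide")
    s1 = sig[..., 0]
    s2 = sig[..., 1]
    w = (s1 * c2 - s2 * c1) / det
    f = (s2 - s1) / det
    return np.abs(w), np.abs(f)


def dualecho_ff(water: np.ndarray, fat: np.ndarray) -> np.ndarray:
    """Fat-fraction map ``F/(W+F)``; NaN where the total signal is zero."""
    water = np.asarray(water, dtype=float)
    fat = np.asarray(fat, dtype=float)
    if water.shape != fat.shape:
        raise ValueError("water and fat images must share a shape")
    if np.any(water < 0) or np.any(fat < 0):
        raise ValueError("water and fat signals must be non-negative")
    total = water + fat
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > 0, fat / total, np.nan)
    return ff
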