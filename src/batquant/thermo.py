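"""Radiometric infrared thermography: raw camera signal to skin temperature.

The camera sees a mixture of object emission, reflected ambient emission and
atmospheric emission:

    raw = eps*tau*S(T_obj) + (1-eps)*tau*S(T_refl) + (1-tau)*S(T_atm)

where ``S(T)`` is a Planck-law signal proxy with camera calibration constants
and ``tau`` the atmospheric transmission along the camera-object path
(a function of distance, air temperature and relative humidity).  Recovering
the object temperature inverts this compensation.  ROI time-window means
(pre-cooling minutes 1-5 and the final 10 minutes of cooling) summarise the
supraclavicular and paranasal skin temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Environment",
    "PlanckConstants",
    "ThermalSeries",
    "atmospheric_transmission",
    "temperature_to_signal",
    "signal_to_temperature",
    "raw_to_temperature",
    "impute_humidity",
    "window_means",
]

# Standard atmospheric-transmission constants of the two-path water-vapour
# attenuation model used by radiometric IR cameras.
ATM_X = 1.9
ATM_ALPHA1 = 0.006569
ATM_ALPHA2 = 0.01262
ATM_BETA1 = -0.002276
ATM_BETA2 = -0.00667
ATM_H = (1.5587, 0.06939, -2.7816e-4, 6.8455e-7)

KELVIN = 273.15


@dataclass(frozen=True)
class Environment:
    """Measurement conditions of one thermography session."""

    distance_m: float = 1.1
    atmospheric_temperature_c: float = 15.0
    relative_humidity: float | None = 0.29  # fraction; None = missing
    emissivity: float = 0.98
    reflected_temperature_c: float | None = None  # default: same as atmospheric

    def __post_init__(self) -> None:
        if not 0 < self.emissivity <= 1:
            raise ValueError("emissivity must be in (0, 1]")
        if self.relative_humidity is not None and not 0 <= self.relative_humidity <= 1:
            raise ValueError("relative humidity must be a fraction in [0, 1]")
        if self.distance_m < 0:
            raise ValueError("distance must be non-negative")
        if self.reflected_temperature_c is None:
            object.__setattr__(
                self, "reflected_temperature_c", self.atmospheric_temperature_c
            )


@dataclass(frozen=True)
class PlanckConstants:
    """Camera calibration constants of the Planck signal proxy
    ``S = R1 / (R2*(exp(B/T_K) - F)) + O`` (documented defaults; real
    cameras carry their own factory calibration)."""

    r1: float = 21106.77
    r2: float = 0.012545258
    b: float = 1501.0682
    o: float = -7340.0
    f: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("B must be positive")


@dataclass
class ThermalSeries:
    """Per-minute temperature frames with SCF and PNR region masks."""

    frames_c: np.ndarray  # (n_frames, H, W)
    scf_mask: np.ndarray
    pnr_mask: np.ndarray
    timestamps_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames_c = np.asarray(self.frames_c, dtype=float)
        self.scf_mask = np.asarray(self.scf_mask) > 0
        self.pnr_mask = np.asarray(self.pnr_mask) > 0
        if self.frames_c.ndim != 3:
            raise ValueError("frames must be (n_frames, H, W)")
        if self.scf_mask.shape != self.frames_c.shape[1:]:
            raise ValueError("SCF mask must match the frame shape")
        if self.pnr_mask.shape != self.frames_c.shape[1:]:
            raise ValueError("PNR mask must match the frame shape")
        if self.timestamps_min is None:
            self.timestamps_min = np.arange(1, self.frames_c.shape[0] + 1, dtype=float)


def atmospheric_transmission(env: Environment) -> float:
    """Atmospheric transmission tau in (0, 1] along the object-camera path."""
    if env.relative_humidity is None:
        raise ValueError("relative humidity missing; impute it first")
    t = env.atmospheric_temperature_c
    h1, h2, h3, h4 = ATM_H
    omega = env.relative_humidity * np.exp(h1 + h2 * t + h3 * t**2 + h4 * t**3)
    sqd = np.sqrt(env.distance_m)
    tau = ATM_X * np.exp(-sqd * (ATM_ALPHA1 + ATM_BETA1 * np.sqrt(omega))) + (
        1.0 - ATM_X
    ) * np.exp(-sqd * (ATM_ALPHA2 + ATM_BETA2 * np.sqrt(omega)))
    return float(tau)


def temperature_to_signal(temp_c, pc: PlanckConstants = PlanckConstants()):
    """Planck-proxy camera signal of a blackbody at ``temp_c`` (deg C)."""
    t_k = np.asarray(temp_c, dtype=float) + KELVIN
    if np.any(t_k <= 0):
        raise ValueError("temperature below 0 K")
    out = pc.r1 / (pc.r2 * (np.exp(pc.b / t_k) - pc.f)) + pc.o
    return out if out.ndim else float(out)


def signal_to_temperature(signal, pc: PlanckConstants = PlanckConstants()):
    """Inverse of :func:`temperature_to_signal`; NaN outside the invertible
    range (signal must exceed the offset ``O``)."""
    s = np.asarray(signal, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg = pc.r1 / (pc.r2 * (s - pc.o)) + pc.f
        t_k = np.where(arg > 1.0, pc.b / np.log(np.where(arg > 1.0, arg, 2.0)), np.nan)
    out = t_k - KELVIN
    return out if out.ndim else float(out)


def raw_to_temperature(
    raw, env: Environment, pc: PlanckConstants = PlanckConstants()
):
    """Object temperature from a raw radiometric signal.

    Removes the reflected and atmospheric contributions, divides by
    emissivity times transmission, and inverts the Planck proxy.  Pixels
    whose compensated signal leaves the invertible range come back as NaN.
    """
    tau = atmospheric_transmission(env)
    if not (env.emissivity > 0 and tau > 0):
        raise ValueError("emissivity and transmission must be positive")
    raw = np.asarray(raw, dtype=float)
    s_refl = temperature_to_signal(env.reflected_temperature_c, pc)
    s_atm = temperature_to_signal(env.atmospheric_temperature_c, pc)
    s_obj = (raw - (1 - env.emissivity) * tau * s_refl - (1 - tau) * s_atm) / (
        env.emissivity * tau
    )
    return signal_to_temperature(s_obj, pc)


def impute_humidity(envs: list[Environment]) -> list[Environment]:
    """Fill missing relative-humidity values with the mean of the present
    ones; present values are untouched."""
    present = [e.relative_humidity for e in envs if e.relative_humidity is not None]
    if not present:
        raise ValueError("no humidity measurement present in any record")
    mean = float(np.mean(present))
    return [
        e if e.relative_humidity is not None else replace(e, relative_humidity=mean)
        for e in envs
    ]


def window_means(series: ThermalSeries) -> dict[str, float]:
    """SCF/PNR means over the neutral (first 5 frames) and cold (final 10
    frames) windows; each window value is the mean of per-frame ROI means."""
    n = series.frames_c.shape[0]
    if n < 15:
        raise ValueError("need at least 15 frames for the 5+10 minute windows")
    if not series.scf_mask.any() or not series.pnr_mask.any():
        raise ValueError("empty ROI mask")
    per_frame = {
        "scf": series.frames_c[:, series.scf_mask].mean(axis=1),
        "pnr": series.frames_c[:, series.pnr_mask].mean(axis=1),
    }
    out = {}
    for roi, vals in per_frame.items():
        out[f"{roi}_neutral_c"] = float(vals[:5].mean())
        out[f"{roi}_cold_c"] = float(vals[-10:].mean())
    return out
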