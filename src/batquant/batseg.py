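"""BAT segmentation and depot summary measurements.

Implements the mask-construction rules used to quantify brown adipose tissue:
a glucose-uptake-rate threshold segmentation (GUR > 10 umol/100 ml/min, minus
a removal mask standing in for manual editing), the fat-fraction/erosion/R2*
refinement of a rough multi-echo delineation (remove FF < 40%, 6-neighbourhood
erode, remove R2* > 120 1/s, in that order), a dual-echo fat mask
(FF >= 40% then erode), slice-exclusion bookkeeping, grid resampling, and the
depot summaries (total GUR, mean FF, mean R2*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .kinetics import GURMap

__all__ = [
    "MaskVolume",
    "DepotSummary",
    "resample_to_grid",
    "exclude_slices",
    "initial_bat_mask",
    "total_gur",
    "erode6",
    "refine_bat_mask",
    "fat_mask",
    "depot_summary",
]

GUR_THRESHOLD = 10.0  # umol/100 ml/min, strict >
FF_MIN = 0.40  # refinement removes FF < 0.40; fat mask keeps FF >= 0.40
R2S_MAX = 120.0  # 1/s, refinement removes R2* > 120

#: face-connected (6-neighbourhood) structuring element
STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class MaskVolume:
    """Binary mask on a voxel grid with a provenance tag."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tag: str = "initial"  # initial | refined | fat-mask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0

    @property
    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class DepotSummary:
    """Per-subject depot measurements; NaN where a mask was empty."""

    total_gur_umol_min: float
    mean_ff: float
    mean_r2s: float
    voxel_count: int
    defined: bool = True


def resample_to_grid(
    src: np.ndarray,
    src_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    order: int = 1,
) -> np.ndarray:
    """Resample a volume onto a target grid via the two voxel-to-world affines.

    ``order=1`` gives trilinear interpolation (maps); use ``order=0``
    (nearest-neighbour) for masks to preserve binarity.
    """
    src = np.asarray(src, dtype=float)
    src_affine = np.asarray(src_affine, dtype=float)
    target_affine = np.asarray(target_affine, dtype=float)
    # target voxel index -> world -> source voxel index
    m = np.linalg.inv(src_affine) @ target_affine
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in target_shape], indexing="ij")
    idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    coords = (m @ idx)[:3]
    inside = np.all(
        (coords >= -0.5)
        & (coords <= (np.array(src.shape)[:, None] - 0.5)),
        axis=0,
    )
    if not inside.any():
        raise ValueError("source and target fields of view do not overlap")
    out = ndimage.map_coordinates(src, coords, order=order, mode="constant", cval=0.0)
    return out.reshape(target_shape)


def exclude_slices(volume: np.ndarray, n_inferior: int, n_superior: int, axis: int = 2):
    """Zero the ``n_inferior`` lowest and ``n_superior`` highest slices.

    Returns a copy; for measurement volumes the zeroed slices must also be
    excluded from any mask, which this achieves when applied to the mask.
    """
    volume = np.asarray(volume)
    n = volume.shape[axis]
    if n_inferior < 0 or n_superior < 0:
        raise ValueError("slice exclusion counts must be non-negative")
    if n_inferior + n_superior >= n:
        raise ValueError(
            f"cannot exclude {n_inferior}+{n_superior} slices from a {n}-slice volume"
        )
    out = volume.copy()
    sl = [slice(None)] * volume.ndim
    if n_inferior:
        sl[axis] = slice(0, n_inferior)
        out[tuple(sl)] = 0
    if n_superior:
        sl[axis] = slice(n - n_superior, n)
        out[tuple(sl)] = 0
    return out


def initial_bat_mask(
    gur: GURMap,
    threshold: float = GUR_THRESHOLD,
    removal_mask: np.ndarray | None = None,
) -> MaskVolume:
    """Threshold segmentation: voxels with GUR strictly above ``threshold``,
    minus the removal mask (the file-based stand-in for manual cleanup)."""
    mask = gur.data > threshold
    if removal_mask is not None:
        removal = np.asarray(removal_mask) > 0
        if removal.shape != mask.shape:
            raise ValueError("removal mask grid does not match the GUR map")
        mask = mask & ~removal
    return MaskVolume(mask, gur.voxel_size_mm, tag="initial")


def total_gur(gur: GURMap, mask: MaskVolume) -> float:
    """Total depot GUR in umol/min: sum of voxel GUR times voxel volume / 100."""
    if mask.data.shape != gur.data.shape:
        raise ValueError("mask grid does not match the GUR map")
    return float(gur.data[mask.data].sum() * gur.voxel_volume_ml / 100.0)


def erode6(mask: MaskVolume | np.ndarray) -> MaskVolume | np.ndarray:
    """6-neighbourhood erosion; voxels on the volume border are eroded away
    (out-of-volume neighbours count as background)."""
    if isinstance(mask, MaskVolume):
        data = ndimage.binary_erosion(mask.data, STRUCT6, border_value=0)
        return MaskVolume(data, mask.voxel_size_mm, tag=mask.tag)
    return ndimage.binary_erosion(np.asarray(mask) > 0, STRUCT6, border_value=0)


def refine_bat_mask(
    rough: MaskVolume,
    ff: np.ndarray,
    r2s: np.ndarray,
    ff_min: float = FF_MIN,
    r2s_max: float = R2S_MAX,
) -> MaskVolume:
    """Refine a rough BAT delineation: remove FF < ff_min, erode with the
    6-neighbourhood element, then remove R2* > r2s_max (strict inequalities,
    applied in exactly that order)."""
    ff = np.asarray(ff, dtype=float)
    r2s = np.asarray(r2s, dtype=float)
    if ff.shape != rough.data.shape or r2s.shape != rough.data.shape:
        raise ValueError("FF/R2* grids do not match the rough mask")
    with np.errstate(invalid="ignore"):
        step1 = rough.data & ~(ff < ff_min)  # NaN FF survives comparison as False
        step1 &= np.isfinite(ff)
        step2 = ndimage.binary_erosion(step1, STRUCT6, border_value=0)
        step3 = step2 & ~(r2s > r2s_max) & np.isfinite(r2s)
    return MaskVolume(step3, rough.voxel_size_mm, tag="refined")


def fat_mask(
    ff: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    ff_min: float = FF_MIN,
) -> MaskVolume:
    """Fat mask: include FF >= ff_min (inclusive), then 6-neighbourhood erode."""
    ff = np.asarray(ff, dtype=float)
    with np.errstate(invalid="ignore"):
        keep = np.isfinite(ff) & (ff >= ff_min)
    return MaskVolume(
        ndimage.binary_erosion(keep, STRUCT6, border_value=0), voxel_size_mm, "fat-mask"
    )


def _masked_mean(values: np.ndarray, mask: np.ndarray) -> float:
    sel = values[mask]
    sel = sel[np.isfinite(sel)]
    return float(sel.mean()) if sel.size else float("nan")


def depot_summary(
    gur: GURMap | None = None,
    bat_mask: MaskVolume | None = None,
    ff: np.ndarray | None = None,
    ff_mask: MaskVolume | None = None,
    r2s: np.ndarray | None = None,
    r2s_mask: MaskVolume | None = None,
) -> DepotSummary:
    """Summarise a depot: total GUR over the BAT mask and mean FF / mean R2*
    over their respective masks.  An empty mask yields NaN and marks the
    summary as undefined rather than raising."""
    tot = float("nan")
    count = 0
    defined = True
    if gur is not None and bat_mask is not None:
        count = bat_mask.count
        if count:
            tot = total_gur(gur, bat_mask)
        else:
            defined = False
    mean_ff = float("nan")
    if ff is not None and ff_mask is not None:
        if ff_mask.count:
            mean_ff = _masked_mean(np.asarray(ff, dtype=float), ff_mask.data)
        else:
            defined = False
    mean_r2s = float("nan")
    if r2s is not None and r2s_mask is not None:
        if r2s_mask.count:
            mean_r2s = _masked_mean(np.asarray(r2s, dtype=float), r2s_mask.data)
        else:
            defined = False
    return DepotSummary(tot, mean_ff, mean_r2s, count, defined)
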