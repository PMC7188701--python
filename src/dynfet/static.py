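"""Static PET quantification: summed image, reference statistics, TBR, MTV.

The evaluation image is the duration-weighted mean SUV over the 20-40 min
post-injection window.  Tumour-to-brain ratios (TBR) divide tumour ROI mean
SUV by the mean SUV of a healthy-brain reference region.  The metabolic
tumour volume (MTV) is the volume of the connected 3D region with
TBR >= 1.6 around the hottest voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .io import DynamicPETSeries, RegionMask, VolumeImage

__all__ = [
    "ReferenceStats",
    "StaticParams",
    "sum_frames",
    "reference_stats",
    "find_max_voxel",
    "tbr_max",
    "autocontour_2d",
    "mtv_3d",
    "compute_static_params",
]

DEFAULT_TBR_THRESHOLD = 1.6
DEFAULT_ROI_DIAMETER_MM = 16.0
DEFAULT_SUM_WINDOW_MIN = (20.0, 40.0)


@dataclass(frozen=True)
class ReferenceStats:
    """Healthy-brain reference: mean SUV (the TBR denominator) and size."""

    mean_suv: float
    voxel_count: int

    def __post_init__(self):
        if not np.isfinite(self.mean_suv) or self.mean_suv <= 0:
            raise ValidationError(
                f"reference mean SUV must be positive and finite, got "
                f"{self.mean_suv} (TBRs divide by it)"
            )


@dataclass
class StaticParams:
    """TBR_max, TBR_mean and MTV, with the max-uptake voxel they derive from.

    When no voxel reaches the TBR threshold (``tumour_detected`` False),
    ``mtv_ml`` is 0 and ``tbr_mean`` is NaN.
    """

    tbr_max: float
    tbr_mean: float
    mtv_ml: float
    max_voxel: tuple[int, int, int]
    tumour_detected: bool


def sum_frames(
    series: DynamicPETSeries,
    window_min: tuple[float, float] = DEFAULT_SUM_WINDOW_MIN,
) -> VolumeImage:
    """Duration-weighted mean SUV over all frames inside ``window_min``.

    The window must coincide with frame boundaries of the schema; for the
    default 16-frame schema and the 20-40 min window these are the four
    5-min frames, weighted equally.
    """
    start_s, end_s = window_min[0] * 60.0, window_min[1] * 60.0
    boundaries = set(series.schema.start_s) | set(series.schema.end_s)
    if start_s not in boundaries or end_s not in boundaries:
        avail = sorted(b / 60.0 for b in boundaries)
        raise ValidationError(
            f"summation window {window_min} min does not align with frame "
            f"boundaries; available boundaries (min): {avail}"
        )
    inside = (series.schema.start_s >= start_s) & (series.schema.end_s <= end_s)
    if not inside.any():
        raise ValidationError(f"no frames inside window {window_min} min")
    durations = series.schema.duration_s[inside]
    frames = series.voxels[inside]
    summed = np.tensordot(durations, frames, axes=(0, 0)) / durations.sum()
    return VolumeImage(summed, series.spacing_mm)


def reference_stats(image: VolumeImage, ref_mask: RegionMask) -> ReferenceStats:
    """Arithmetic mean SUV over the reference-region voxels."""
    ref_mask.require_nonempty("reference region")
    ref_mask.check_grid(image.voxels.shape, image.spacing_mm)
    values = image.voxels[ref_mask.voxels]
    return ReferenceStats(mean_suv=float(values.mean()), voxel_count=len(values))


def find_max_voxel(
    image: VolumeImage, search_mask: RegionMask | None = None
) -> tuple[int, int, int]:
    """Index of the hottest voxel (ties -> lowest (z, y, x) lexicographically)."""
    data = image.voxels
    if search_mask is not None:
        search_mask.require_nonempty("search mask")
        search_mask.check_grid(data.shape, image.spacing_mm)
        data = np.where(search_mask.voxels, data, -np.inf)
    # np.argmax scans in C order, which is exactly lexicographic (z, y, x)
    flat = int(np.argmax(data))
    return tuple(int(i) for i in np.unravel_index(flat, data.shape))


def _disc_offsets(
    spacing_mm: tuple[float, float, float], diameter_mm: float
) -> list[tuple[int, int]]:
    """In-plane (dy, dx) voxel offsets whose centre lies within the disc."""
    _, sy, sx = spacing_mm
    r = diameter_mm / 2.0
    ny = int(np.floor(r / sy))
    nx = int(np.floor(r / sx))
    return [
        (dy, dx)
        for dy in range(-ny, ny + 1)
        for dx in range(-nx, nx + 1)
        if (dy * sy) ** 2 + (dx * sx) ** 2 <= r * r
    ]


def tbr_max(
    image: VolumeImage,
    ref: ReferenceStats,
    max_voxel: tuple[int, int, int],
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> float:
    """TBR_max: mean SUV of a 1.6 cm in-plane disc at the hottest voxel,
    divided by the reference mean.

    The disc lives in the transversal (fixed z) slice; membership is by
    voxel-centre distance, which handles anisotropic in-plane spacing.
    """
    z, y, x = max_voxel
    _, ny, nx = image.voxels.shape
    values = []
    clipped = False
    for dy, dx in _disc_offsets(image.spacing_mm, roi_diameter_mm):
        yy, xx = y + dy, x + dx
        if 0 <= yy < ny and 0 <= xx < nx:
            values.append(image.voxels[z, yy, xx])
        else:
            clipped = True
    if clipped:
        warnings.warn(
            "TBR_max disc extends beyond the image bounds; clipped to the "
            "field of view",
            stacklevel=2,
        )
    if not values:
        raise GeometryError("TBR_max disc lies fully outside the image")
    return float(np.mean(values)) / ref.mean_suv


_STRUCT_2D = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
_STRUCT_3D = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def autocontour_2d(
    image: VolumeImage,
    ref: ReferenceStats,
    max_voxel: tuple[int, int, int],
    tbr_threshold: float = DEFAULT_TBR_THRESHOLD,
) -> tuple[RegionMask | None, float]:
    """2D auto-contour in the transversal slice of the hottest voxel.

    Returns the 4-connected component of voxels with
    SUV >= threshold x reference mean that contains the hottest voxel, and
    TBR_mean over that component.  If even the hottest voxel is below the
    threshold, no tumour is detected: returns ``(None, nan)``.
    """
    z, y, x = max_voxel
    slc = image.voxels[z]
    above = slc >= tbr_threshold * ref.mean_suv
    if not above[y, x]:
        return None, float("nan")
    labels, _ = ndimage.label(above, structure=_STRUCT_2D)
    component = labels == labels[y, x]
    mask = np.zeros(image.voxels.shape, dtype=bool)
    mask[z] = component
    tbr_mean = float(slc[component].mean()) / ref.mean_suv
    return RegionMask(mask, image.spacing_mm), tbr_mean


def mtv_3d(
    image: VolumeImage,
    ref: ReferenceStats,
    max_voxel: tuple[int, int, int],
    tbr_threshold: float = DEFAULT_TBR_THRESHOLD,
) -> tuple[RegionMask | None, float]:
    """3D auto-contour and metabolic tumour volume.

    Returns the 6-connected 3D component of voxels with
    SUV >= threshold x reference mean that contains the hottest voxel, and
    its volume in mL (voxel count x voxel volume).  ``(None, 0.0)`` when the
    hottest voxel is below the threshold.
    """
    z, y, x = max_voxel
    above = image.voxels >= tbr_threshold * ref.mean_suv
    if not above[z, y, x]:
        return None, 0.0
    labels, _ = ndimage.label(above, structure=_STRUCT_3D)
    component = labels == labels[z, y, x]
    mtv_ml = float(component.sum()) * image.voxel_volume_ml
    return RegionMask(component, image.spacing_mm), mtv_ml


def compute_static_params(
    image: VolumeImage,
    ref: ReferenceStats,
    search_mask: RegionMask | None = None,
    tbr_threshold: float = DEFAULT_TBR_THRESHOLD,
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> StaticParams:
    """All static parameters from an evaluation image and reference stats."""
    mv = find_max_voxel(image, search_mask)
    t_max = tbr_max(image, ref, mv, roi_diameter_mm)
    _, t_mean = autocontour_2d(image, ref, mv, tbr_threshold)
    mask3d, mtv = mtv_3d(image, ref, mv, tbr_threshold)
    return StaticParams(
        tbr_max=t_max,
        tbr_mean=t_mean,
        mtv_ml=mtv,
        max_voxel=mv,
        tumour_detected=mask3d is not None,
    )
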