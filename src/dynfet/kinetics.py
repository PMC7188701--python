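"""Dynamic PET quantification: time-activity curves, time-to-peak, slope.

The tumour TAC is the frame-wise mean SUV inside a 2 mL spherical VOI
centred on the hottest voxel of the 20-40 min evaluation image.  Two
kinetic parameters summarize it:

* **TTP** — minutes from the start of the acquisition through the frame
  with the maximum uptake (frame end time; earliest frame on ties).  A
  steadily increasing curve has no identifiable peak, and TTP is set to
  the acquisition end (50 min for the default schema).
* **slope** — the ordinary least-squares slope of uptake against frame
  mid-time over the late phase (20-50 min), expressed in SUV per hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, StageError, ValidationError
from .io import DynamicPETSeries, RegionMask
from .static import (
    DEFAULT_ROI_DIAMETER_MM,
    DEFAULT_SUM_WINDOW_MIN,
    DEFAULT_TBR_THRESHOLD,
    StaticParams,
    compute_static_params,
    reference_stats,
    sum_frames,
)

__all__ = [
    "TimeActivityCurve",
    "KineticParams",
    "PatientQuantification",
    "voi_radius_mm",
    "sphere_voxel_offsets",
    "extract_tac",
    "compute_ttp",
    "compute_slope",
    "compute_kinetic_params",
    "quantify_patient",
]

DEFAULT_VOI_VOLUME_ML = 2.0
DEFAULT_SLOPE_WINDOW_MIN = (20.0, 50.0)


@dataclass
class TimeActivityCurve:
    """Mean SUV per frame with the frame mid- and end-times in minutes."""

    frame_mid_min: np.ndarray
    frame_end_min: np.ndarray
    mean_suv: np.ndarray

    def __post_init__(self):
        self.frame_mid_min = np.asarray(self.frame_mid_min, dtype=float)
        self.frame_end_min = np.asarray(self.frame_end_min, dtype=float)
        self.mean_suv = np.asarray(self.mean_suv, dtype=float)
        n = len(self.mean_suv)
        if len(self.frame_mid_min) != n or len(self.frame_end_min) != n:
            raise ValidationError("TAC time and value vectors differ in length")
        for t in (self.frame_mid_min, self.frame_end_min):
            if np.any(np.diff(t) <= 0):
                raise ValidationError("TAC times must be strictly increasing")
        if not np.all(np.isfinite(self.mean_suv)) or np.any(self.mean_suv < 0):
            raise ValidationError("TAC values must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.mean_suv)

    @property
    def acquisition_end_min(self) -> float:
        return float(self.frame_end_min[-1])


@dataclass
class KineticParams:
    """TTP (minutes) and late-phase slope (SUV/h).

    ``peak_identified`` is False for steadily increasing curves, in which
    case TTP equals the acquisition end.
    """

    ttp_min: float
    slope_suv_per_h: float
    peak_identified: bool


def voi_radius_mm(voi_volume_ml: float = DEFAULT_VOI_VOLUME_ML) -> float:
    """Radius of a sphere of the given volume ((4/3) pi r^3 = V); ~7.816 mm
    for the standard 2 mL VOI."""
    return float((3.0 * voi_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def sphere_voxel_offsets(
    spacing_mm: tuple[float, float, float], radius_mm: float
) -> np.ndarray:
    """(dz, dy, dx) index offsets of voxels whose centres lie within
    ``radius_mm`` of a voxel centre."""
    sz, sy, sx = spacing_mm
    nz = int(np.floor(radius_mm / sz))
    ny = int(np.floor(radius_mm / sy))
    nx = int(np.floor(radius_mm / sx))
    dz, dy, dx = np.mgrid[-nz : nz + 1, -ny : ny + 1, -nx : nx + 1]
    within = (dz * sz) ** 2 + (dy * sy) ** 2 + (dx * sx) ** 2 <= radius_mm**2
    return np.stack([dz[within], dy[within], dx[within]], axis=1)


def extract_tac(
    series: DynamicPETSeries,
    centre_voxel: tuple[int, int, int],
    voi_volume_ml: float = DEFAULT_VOI_VOLUME_ML,
) -> TimeActivityCurve:
    """Mean SUV per frame over a spherical VOI centred on ``centre_voxel``.

    Voxel membership is by centre-in-sphere using physical distances; the
    sphere is clipped at the field of view, but must intersect it.
    """
    r = voi_radius_mm(voi_volume_ml)
    offsets = sphere_voxel_offsets(series.spacing_mm, r)
    idx = offsets + np.asarray(centre_voxel)
    shape = series.spatial_shape
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    if not ok.any():
        raise GeometryError(
            f"VOI sphere around voxel {centre_voxel} lies fully outside the "
            f"image (shape {shape})"
        )
    zz, yy, xx = idx[ok, 0], idx[ok, 1], idx[ok, 2]
    values = series.voxels[:, zz, yy, xx].mean(axis=1)
    return TimeActivityCurve(
        frame_mid_min=series.schema.mid_min,
        frame_end_min=series.schema.end_min,
        mean_suv=values,
    )


def extract_mask_tac(
    series: DynamicPETSeries, mask: RegionMask
) -> TimeActivityCurve:
    """Mean SUV per frame over an arbitrary mask (e.g. the reference ROI)."""
    mask.require_nonempty()
    mask.check_grid(series.spatial_shape, series.spacing_mm)
    values = series.voxels[:, mask.voxels].mean(axis=1)
    return TimeActivityCurve(
        frame_mid_min=series.schema.mid_min,
        frame_end_min=series.schema.end_min,
        mean_suv=values,
    )


def compute_ttp(
    tac: TimeActivityCurve, use_mid_times: bool = False
) -> tuple[float, bool]:
    """Time-to-peak of a TAC.

    TTP is the end time (or mid time, behind the ``use_mid_times`` flag) of
    the earliest frame attaining the global maximum.  If that frame is the
    final one, the curve is treated as steadily increasing with no
    identifiable peak: ``peak_identified`` is False and TTP is the
    acquisition end.
    """
    if tac.n_frames < 2:
        raise ValidationError("TTP needs at least 2 frames")
    peak_frame = int(np.argmax(tac.mean_suv))  # argmax takes the earliest tie
    if np.all(tac.mean_suv == tac.mean_suv[0]):
        warnings.warn(
            "constant TAC: TTP set to the first frame by the earliest-"
            "maximum rule",
            stacklevel=2,
        )
    if peak_frame == tac.n_frames - 1:
        return tac.acquisition_end_min, False
    times = tac.frame_mid_min if use_mid_times else tac.frame_end_min
    return float(times[peak_frame]), True


def compute_slope(
    tac: TimeActivityCurve,
    window_min: tuple[float, float] = DEFAULT_SLOPE_WINDOW_MIN,
) -> float:
    """Late-phase slope in SUV/h: OLS fit of mean SUV against frame mid-time
    over frames whose mid-time falls inside ``window_min``, scaled from
    per-minute to per-hour."""
    start, end = window_min
    inside = (tac.frame_mid_min >= start) & (tac.frame_mid_min <= end)
    if inside.sum() < 2:
        raise ValidationError(
            f"slope window {window_min} min contains {int(inside.sum())} "
            f"frame mid-times; need at least 2"
        )
    t = tac.frame_mid_min[inside]
    y = tac.mean_suv[inside]
    slope_per_min = np.polyfit(t, y, 1)[0]
    return float(slope_per_min * 60.0)


def compute_kinetic_params(
    tac: TimeActivityCurve,
    slope_window_min: tuple[float, float] = DEFAULT_SLOPE_WINDOW_MIN,
    use_mid_times: bool = False,
) -> KineticParams:
    ttp, peak = compute_ttp(tac, use_mid_times=use_mid_times)
    slope = compute_slope(tac, slope_window_min)
    return KineticParams(ttp_min=ttp, slope_suv_per_h=slope, peak_identified=peak)


@dataclass
class PatientQuantification:
    """Bundle of everything quantified for one patient."""

    static: StaticParams
    kinetic: KineticParams
    tumour_tac: TimeActivityCurve
    reference_tac: TimeActivityCurve | None = None


def quantify_patient(
    series: DynamicPETSeries,
    ref_mask: RegionMask,
    sum_window_min: tuple[float, float] = DEFAULT_SUM_WINDOW_MIN,
    tbr_threshold: float = DEFAULT_TBR_THRESHOLD,
    roi_diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
    voi_volume_ml: float = DEFAULT_VOI_VOLUME_ML,
    slope_window_min: tuple[float, float] = DEFAULT_SLOPE_WINDOW_MIN,
    search_mask: RegionMask | None = None,
    use_mid_times: bool = False,
    include_reference_tac: bool = True,
) -> PatientQuantification:
    """Full static + dynamic quantification of one dynamic series.

    Deterministic composition: summed 20-40 min image -> reference stats ->
    hottest voxel -> {TBR_max, 2D auto-contour, 3D MTV} and 2 mL VOI TAC ->
    {TTP, slope}.  Stage errors are re-raised with the stage name attached.
    """

    def run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(stage, exc) from exc

    image = run("sum_frames", sum_frames, series, sum_window_min)
    ref = run("reference_stats", reference_stats, image, ref_mask)
    static = run(
        "static_params",
        compute_static_params,
        image,
        ref,
        search_mask=search_mask,
        tbr_threshold=tbr_threshold,
        roi_diameter_mm=roi_diameter_mm,
    )
    tac = run("extract_tac", extract_tac, series, static.max_voxel, voi_volume_ml)
    kinetic = run(
        "kinetic_params",
        compute_kinetic_params,
        tac,
        slope_window_min=slope_window_min,
        use_mid_times=use_mid_times,
    )
    ref_tac = None
    if include_reference_tac:
        ref_tac = run("reference_tac", extract_mask_tac, series, ref_mask)
    return PatientQuantification(
        static=static, kinetic=kinetic, tumour_tac=tac, reference_tac=ref_tac
    )


def tac_to_frame(tac: TimeActivityCurve, reference: TimeActivityCurve | None = None):
    """TAC as a DataFrame for CSV export."""
    import pandas as pd

    start_s = (2.0 * tac.frame_mid_min - tac.frame_end_min) * 60.0
    df = pd.DataFrame(
        {
            "frame_index": np.arange(tac.n_frames),
            "start_s": start_s,
            "end_s": tac.frame_end_min * 60.0,
            "mid_min": tac.frame_mid_min,
            "tumour_mean_suv": tac.mean_suv,
        }
    )
    if reference is not None:
        df["reference_mean_suv"] = reference.mean_suv
    return df
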