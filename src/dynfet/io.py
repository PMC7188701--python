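"""Reading and writing dynamic PET series, masks, frame schemas and cohorts.

All quantification in this package operates on standardized uptake values
(SUV = activity concentration / (injected dose / body weight)).  Conversion
from raw activity (Bq/mL) happens once, at ingest; downstream modules never
see calibration metadata.

Voxel arrays use array index order ``(z, y, x)`` (frames first for 4D data)
with voxel spacing ``spacing_mm = (dz, dy, dx)``.  Masks must live on the
identical grid as the image they annotate; no resampling is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import CalibrationError, GridMismatchError, ValidationError

__all__ = [
    "FrameSchema",
    "CalibrationInfo",
    "DynamicPETSeries",
    "VolumeImage",
    "RegionMask",
    "default_frame_schema",
    "read_frame_schema",
    "write_frame_schema",
    "read_dynamic_series",
    "write_dynamic_series",
    "read_mask",
    "write_mask",
    "read_volume",
    "write_volume",
    "read_calibration",
    "gaussian_smooth",
]

#: the default acquisition: 16 frames, 5 x 1 min, 5 x 3 min, 6 x 5 min (0-50 min)
_DEFAULT_FRAME_DURATIONS_S = (60,) * 5 + (180,) * 5 + (300,) * 6


@dataclass(frozen=True)
class FrameSchema:
    """Timing of a dynamic acquisition: ordered ``(start_s, end_s)`` pairs.

    Frames must be contiguous, non-overlapping and strictly increasing,
    starting at t = 0.
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValidationError("frame schema must contain at least one frame")
        prev_end = 0.0
        if self.frames[0][0] != 0.0:
            raise ValidationError(
                f"first frame must start at 0 s, got {self.frames[0][0]} s"
            )
        for i, (start, end) in enumerate(self.frames):
            if end <= start:
                raise ValidationError(
                    f"frame {i} has non-positive duration ({start}-{end} s)"
                )
            if start != prev_end:
                raise ValidationError(
                    f"frame {i} starts at {start} s but previous frame ended at "
                    f"{prev_end} s (frames must be contiguous)"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_s(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames], dtype=float)

    @property
    def end_s(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames], dtype=float)

    @property
    def duration_s(self) -> np.ndarray:
        return self.end_s - self.start_s

    @property
    def mid_min(self) -> np.ndarray:
        """Frame mid-times in minutes (abscissae for slope regression)."""
        return (self.start_s + self.end_s) / 2.0 / 60.0

    @property
    def end_min(self) -> np.ndarray:
        """Frame end times in minutes (ordinate of the TTP convention)."""
        return self.end_s / 60.0

    @property
    def acquisition_end_min(self) -> float:
        return float(self.frames[-1][1]) / 60.0


def default_frame_schema() -> FrameSchema:
    """The 16-frame 0-50 min schema (5 x 1 min, 5 x 3 min, 6 x 5 min)."""
    frames, t = [], 0.0
    for d in _DEFAULT_FRAME_DURATIONS_S:
        frames.append((t, t + d))
        t += d
    return FrameSchema(tuple(frames))


def read_frame_schema(path: str | Path) -> FrameSchema:
    """Read a frame-timing table (CSV: frame_index, start_s, end_s)."""
    df = pd.read_csv(path)
    required = {"frame_index", "start_s", "end_s"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"frame table {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    df = df.sort_values("frame_index")
    return FrameSchema(tuple(zip(df["start_s"].astype(float), df["end_s"].astype(float))))


def write_frame_schema(schema: FrameSchema, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(len(schema)),
            "start_s": schema.start_s,
            "end_s": schema.end_s,
        }
    ).to_csv(path, index=False)


def packaged_default_schema_path() -> Path:
    """Path of the packaged 16-frame schema fixture."""
    return Path(resources.files("dynfet") / "_data" / "frame_schema_16.csv")


@dataclass(frozen=True)
class CalibrationInfo:
    """SUV calibration metadata.

    ``input_units`` declares the units of the voxel data on disk.  When the
    data are already in SUV, dose and weight are optional; for Bq/mL both are
    required (SUV = concentration / (injected dose [Bq] / body weight [g])).
    """

    input_units: str = "SUV"
    injected_dose_MBq: float | None = None
    body_weight_kg: float | None = None

    def __post_init__(self):
        if self.input_units not in ("SUV", "Bq_per_mL"):
            raise CalibrationError(
                f"input_units must be 'SUV' or 'Bq_per_mL', got {self.input_units!r}"
            )
        if self.input_units == "Bq_per_mL":
            if self.injected_dose_MBq is None or self.body_weight_kg is None:
                raise CalibrationError(
                    "injected_dose_MBq and body_weight_kg are required when "
                    "input_units is 'Bq_per_mL'"
                )
        for name in ("injected_dose_MBq", "body_weight_kg"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise CalibrationError(f"{name} must be positive, got {v}")

    @property
    def suv_scale(self) -> float:
        """Divisor turning Bq/mL into SUV (1.0 if data already in SUV)."""
        if self.input_units == "SUV":
            return 1.0
        dose_bq = self.injected_dose_MBq * 1e6
        weight_g = self.body_weight_kg * 1e3
        return dose_bq / weight_g


def read_calibration(path: str | Path) -> CalibrationInfo:
    """Read a JSON sidecar {injected_dose_MBq, body_weight_kg, input_units}."""
    with open(path) as fh:
        raw = json.load(fh)
    return CalibrationInfo(
        input_units=raw.get("input_units", "SUV"),
        injected_dose_MBq=raw.get("injected_dose_MBq"),
        body_weight_kg=raw.get("body_weight_kg"),
    )


def _check_finite_nonneg(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{what} contains non-finite values")
    if np.any(arr < 0):
        raise ValidationError(f"{what} contains negative values")


@dataclass
class DynamicPETSeries:
    """A 4D dynamic PET image in SUV with frame timing and voxel geometry.

    ``voxels`` has shape ``(n_frames, nz, ny, nx)``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    schema: FrameSchema
    calibration: CalibrationInfo = field(default_factory=CalibrationInfo)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValidationError(
                f"dynamic series must be 4D (frame, z, y, x), got shape "
                f"{self.voxels.shape}"
            )
        if self.voxels.shape[0] != len(self.schema):
            raise ValidationError(
                f"series has {self.voxels.shape[0]} frames but schema has "
                f"{len(self.schema)}"
            )
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be positive, got {self.spacing_mm}")
        _check_finite_nonneg(self.voxels, "dynamic series")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_volume_ml(self) -> float:
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx / 1000.0


@dataclass
class VolumeImage:
    """A single 3D SUV volume (e.g. the summed 20-40 min image)."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValidationError(f"volume must be 3D, got shape {self.voxels.shape}")
        _check_finite_nonneg(self.voxels, "volume image")

    @property
    def voxel_volume_ml(self) -> float:
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx / 1000.0


@dataclass
class RegionMask:
    """A boolean voxel mask grid-congruent with the image it annotates."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValidationError(f"mask must be 3D, got shape {self.voxels.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    def require_nonempty(self, what: str = "mask") -> None:
        if self.n_voxels == 0:
            raise ValidationError(f"{what} is empty")

    def check_grid(self, shape: tuple[int, ...], spacing_mm: Sequence[float]) -> None:
        if self.voxels.shape != tuple(shape) or tuple(self.spacing_mm) != tuple(
            spacing_mm
        ):
            raise GridMismatchError(
                f"mask grid (shape={self.voxels.shape}, spacing={self.spacing_mm}) "
                f"does not match image grid (shape={tuple(shape)}, "
                f"spacing={tuple(spacing_mm)})"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O.  On disk, NIfTI stores (x, y, z[, t]); internally we use
# (t, z, y, x).  A plain transpose maps between the two.
# ---------------------------------------------------------------------------


def _affine(spacing_mm: Sequence[float]) -> np.ndarray:
    dz, dy, dx = spacing_mm
    return np.diag([dx, dy, dz, 1.0])


def read_dynamic_series(
    image_path: str | Path,
    frame_table_path: str | Path | None = None,
    calibration: CalibrationInfo | None = None,
    schema: FrameSchema | None = None,
) -> DynamicPETSeries:
    """Read a 4D NIfTI series and calibrate it to SUV.

    Exactly one of ``frame_table_path`` / ``schema`` may be given; with
    neither, the 16-frame default schema is assumed.
    """
    if calibration is None:
        calibration = CalibrationInfo()
    if frame_table_path is not None and schema is not None:
        raise ValidationError("give either frame_table_path or schema, not both")
    if frame_table_path is not None:
        schema = read_frame_schema(frame_table_path)
    elif schema is None:
        schema = default_frame_schema()

    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValidationError(
            f"{image_path}: expected a 4D NIfTI series, got {data.ndim}D"
        )
    if data.shape[3] != len(schema):
        raise ValidationError(
            f"{image_path}: image has {data.shape[3]} frames but the frame "
            f"table declares {len(schema)}"
        )
    zooms = img.header.get_zooms()[:3]  # (dx, dy, dz)
    spacing_mm = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    voxels = data.T / calibration.suv_scale  # -> (t, z, y, x), SUV
    return DynamicPETSeries(voxels, spacing_mm, schema, calibration)


def write_dynamic_series(series: DynamicPETSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.voxels.T, _affine(series.spacing_mm))
    img.header.set_zooms(
        (series.spacing_mm[2], series.spacing_mm[1], series.spacing_mm[0], 1.0)
    )
    nib.save(img, str(path))


def read_volume(path: str | Path) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D NIfTI volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    return VolumeImage(data.T, (float(zooms[2]), float(zooms[1]), float(zooms[0])))


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.voxels.T, _affine(volume.spacing_mm)), str(path))


def read_mask(
    path: str | Path, reference: DynamicPETSeries | VolumeImage
) -> RegionMask:
    """Read a NIfTI mask (nonzero -> True) and verify grid congruence."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D NIfTI mask, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    mask = RegionMask(data.T != 0, spacing)
    ref_shape = (
        reference.spatial_shape
        if isinstance(reference, DynamicPETSeries)
        else reference.voxels.shape
    )
    mask.check_grid(ref_shape, reference.spacing_mm)
    return mask


def write_mask(mask: RegionMask, path: str | Path) -> None:
    nib.save(
        nib.Nifti1Image(
            mask.voxels.T.astype(np.uint8), _affine(mask.spacing_mm)
        ),
        str(path),
    )


def gaussian_smooth(
    series: DynamicPETSeries, fwhm_mm: float
) -> DynamicPETSeries:
    """Optionally smooth each frame with an isotropic Gaussian (FWHM in mm).

    Off by default in the pipeline; exposed for cross-scanner harmonization
    experiments.
    """
    if fwhm_mm <= 0:
        raise ValidationError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = [sigma_mm / s for s in series.spacing_mm]
    smoothed = np.stack(
        [ndimage.gaussian_filter(f, sigma=sigma_vox) for f in series.voxels]
    )
    return DynamicPETSeries(
        np.clip(smoothed, 0.0, None), series.spacing_mm, series.schema,
        series.calibration,
    )
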