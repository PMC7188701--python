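"""Digital dynamic-PET phantoms and linked survival cohorts.

The phantom emulates the phenomenology a dynamic amino-acid PET pipeline
must handle, not PET physics: a brain-like ellipsoidal background with its
own slowly rising uptake, an embedded spherical tumour whose time-activity
curve follows either a *washout* pattern (early peak, declining late
phase) or a *plateau* pattern (steadily increasing uptake, no identifiable
peak), a contralateral crescent reference region, and a 16-frame 0-50 min
acquisition (5 x 1 min, 5 x 3 min, 6 x 5 min).

The continuous tumour/background curve is

    u(t) = b + A (1 - exp(-t / tau)) exp(-w t)        [t in minutes]

with baseline ``b``, amplitude ``A``, uptake time constant ``tau`` and
washout rate ``w`` (``w = 0`` gives the monotone plateau class).  Frame
values are the exact time-average of ``u`` over each frame interval, so
the estimators' frame-time conventions are exercised; i.i.d. Gaussian
noise (truncated at zero) is added on top.

Every generated object ships with its ground truth: the discretized
noiseless TTP and late-phase slope, the analytic tumour volume, and the
survival-model parameters, so every estimator in the pipeline can be
scored without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import PatientRecord
from .errors import GeometryError, ValidationError
from .io import (
    DynamicPETSeries,
    FrameSchema,
    RegionMask,
    default_frame_schema,
)
from .kinetics import sphere_voxel_offsets, voi_radius_mm

__all__ = [
    "TACModel",
    "PhantomGeometry",
    "SyntheticCohortConfig",
    "PhantomGroundTruth",
    "WASHOUT_TAC",
    "PLATEAU_TAC",
    "BACKGROUND_TAC",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class TACModel:
    """Continuous two-exponential uptake curve for one tissue class."""

    kind: str  # washout | plateau
    amplitude: float  # A, SUV
    tau_up_min: float  # uptake time constant, minutes
    washout_per_min: float  # w, 1/min (0 for the plateau class)
    baseline: float  # b, SUV

    def __post_init__(self):
        if self.kind not in ("washout", "plateau"):
            raise ValidationError(f"unknown TAC class {self.kind!r}")
        if not (self.amplitude > self.baseline >= 0):
            raise ValidationError(
                f"need amplitude > baseline >= 0, got A={self.amplitude}, "
                f"b={self.baseline}"
            )
        if self.tau_up_min <= 0:
            raise ValidationError("tau_up_min must be positive")
        if self.washout_per_min < 0:
            raise ValidationError("washout_per_min must be >= 0")
        if self.kind == "plateau" and self.washout_per_min != 0:
            raise ValidationError("plateau class requires washout_per_min = 0")
        if self.kind == "washout" and self.washout_per_min == 0:
            raise ValidationError("washout class requires washout_per_min > 0")

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return self.baseline + self.amplitude * (
            1.0 - np.exp(-t / self.tau_up_min)
        ) * np.exp(-self.washout_per_min * t)

    @property
    def peak_time_min(self) -> float:
        """Analytic maximum of the continuous curve (inf for plateau)."""
        w, tau = self.washout_per_min, self.tau_up_min
        if w == 0:
            return math.inf
        return tau * math.log(1.0 + 1.0 / (w * tau))

    def frame_averages(self, schema: FrameSchema) -> np.ndarray:
        """Exact time-average of the curve over each frame interval."""
        t0 = schema.start_s / 60.0
        t1 = schema.end_s / 60.0
        dt = t1 - t0

        def integral(k):  # int exp(-k t) dt over [t0, t1]
            if k == 0:
                return dt
            return (np.exp(-k * t0) - np.exp(-k * t1)) / k

        w, tau, a, b = (
            self.washout_per_min,
            self.tau_up_min,
            self.amplitude,
            self.baseline,
        )
        area = b * dt + a * integral(w) - a * integral(w + 1.0 / tau)
        return area / dt

    def validate_peaks_before(self, end_min: float) -> None:
        if self.kind == "washout" and not self.peak_time_min < end_min:
            raise ValidationError(
                f"washout curve peaks at {self.peak_time_min:.1f} min, not "
                f"before the acquisition end ({end_min:.1f} min)"
            )


#: default tumour classes and background, on a realistic FET SUV scale
#: (healthy brain ~1 SUV late; tumour peaks ~2.5-3)
WASHOUT_TAC = TACModel("washout", amplitude=3.0, tau_up_min=4.0,
                       washout_per_min=0.02, baseline=0.5)
PLATEAU_TAC = TACModel("plateau", amplitude=2.5, tau_up_min=12.0,
                       washout_per_min=0.0, baseline=0.5)
BACKGROUND_TAC = TACModel("plateau", amplitude=1.0, tau_up_min=8.0,
                          washout_per_min=0.0, baseline=0.1)


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxel grid, brain ellipsoid and tumour sphere of the digital phantom."""

    shape: tuple[int, int, int] = (32, 40, 40)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tumour_radius_mm: float = 10.0
    tumour_offset_mm: float = 16.0  # lateral (+x) shift from the brain centre
    brain_semiaxes_mm: tuple[float, float, float] = (28.0, 36.0, 36.0)
    tumour_profile_bump: float = 0.1  # parabolic intra-tumour contrast

    def voxel_centres(self):
        """Physical (z, y, x) coordinates of voxel centres, origin at the
        grid centre."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.shape, self.spacing_mm)
        ]
        return np.meshgrid(*axes, indexing="ij")

    @property
    def tumour_centre_index(self) -> tuple[int, int, int]:
        """Voxel index nearest to the tumour centre (on the +x side)."""
        nz, ny, nx = self.shape
        ox = int(round(self.tumour_offset_mm / self.spacing_mm[2]))
        return (nz // 2, ny // 2, nx // 2 + ox)

    def tumour_centre_mm(self) -> tuple[float, float, float]:
        idx = self.tumour_centre_index
        return tuple(
            (i - (n - 1) / 2.0) * s
            for i, n, s in zip(idx, self.shape, self.spacing_mm)
        )

    @property
    def analytic_tumour_volume_ml(self) -> float:
        return 4.0 / 3.0 * math.pi * self.tumour_radius_mm**3 / 1000.0


@dataclass
class PhantomGroundTruth:
    """Everything needed to score the quantification of one phantom."""

    kinetic_class: str
    ttp_min: float
    peak_identified: bool
    slope_suv_per_h: float
    mtv_ml: float  # analytic sphere volume
    tumour_centre_index: tuple[int, int, int]
    continuous_peak_min: float
    voi_tac: np.ndarray = field(repr=False, default=None)
    tumour_tac_model: dict = field(default_factory=dict)


def _ols_slope_per_hour(
    mid_min: np.ndarray, values: np.ndarray, window=(20.0, 50.0)
) -> float:
    """Closed-form OLS slope over the late window, SUV/h (generator-side
    oracle, independent of the quantifier's regression routine)."""
    sel = (mid_min >= window[0]) & (mid_min <= window[1])
    t, y = mid_min[sel], values[sel]
    tc = t - t.mean()
    return float((tc @ (y - y.mean())) / (tc @ tc) * 60.0)


def _discretized_ttp(end_min: np.ndarray, values: np.ndarray) -> tuple[float, bool]:
    """Earliest-global-max frame-end TTP with the steadily-increasing
    fallback (generator-side oracle)."""
    peak = int(np.argmax(values))
    if peak == len(values) - 1:
        return float(end_min[-1]), False
    return float(end_min[peak]), True


def generate_phantom(
    tumour_tac: TACModel = WASHOUT_TAC,
    geometry: PhantomGeometry = PhantomGeometry(),
    background_tac: TACModel = BACKGROUND_TAC,
    noise_sigma: float = 0.0,
    seed: int = 0,
    schema: FrameSchema | None = None,
    voi_volume_ml: float = 2.0,
) -> tuple[DynamicPETSeries, RegionMask, PhantomGroundTruth]:
    """Build a dynamic phantom and its ground truth.

    The tumour sphere carries a mild parabolic uptake profile
    (``1 + bump (1 - (r/R)^2)``, constant over time) so the hottest voxel is
    its centre; the ground-truth VOI curve accounts for that profile and
    for any background mixed into the VOI sphere.
    """
    schema = schema or default_frame_schema()
    end_min = schema.acquisition_end_min
    tumour_tac.validate_peaks_before(end_min)

    geo = geometry
    zc, yc, xc = geo.voxel_centres()
    az, ay, ax = geo.brain_semiaxes_mm
    brain = (zc / az) ** 2 + (yc / ay) ** 2 + (xc / ax) ** 2 <= 1.0
    tz, ty, tx = geo.tumour_centre_mm()
    r2 = (zc - tz) ** 2 + (yc - ty) ** 2 + (xc - tx) ** 2
    tumour = r2 <= geo.tumour_radius_mm**2
    if not tumour.any():
        raise GeometryError("tumour sphere contains no voxels")
    if np.any(tumour & ~brain):
        raise GeometryError("tumour sphere extends outside the brain ellipsoid")
    profile = np.where(
        tumour,
        1.0 + geo.tumour_profile_bump * (1.0 - r2 / geo.tumour_radius_mm**2),
        0.0,
    )

    tum_avg = tumour_tac.frame_averages(schema)
    bg_avg = background_tac.frame_averages(schema)

    # contourability: even the coolest tumour voxel must clear the 1.6x
    # reference threshold on the 20-40 min evaluation image
    eval_sel = (schema.start_s >= 20 * 60) & (schema.end_s <= 40 * 60)
    w = schema.duration_s[eval_sel]
    tum_eval = float(np.average(tum_avg[eval_sel], weights=w))
    bg_eval = float(np.average(bg_avg[eval_sel], weights=w))
    if tum_eval < 1.6 * bg_eval:
        raise ValidationError(
            f"tumour 20-40 min uptake ({tum_eval:.2f} SUV) is below 1.6x the "
            f"background ({bg_eval:.2f} SUV); lesion would not be contourable"
        )

    rng = np.random.default_rng(seed)
    frames = np.empty((len(schema),) + geo.shape)
    for f in range(len(schema)):
        vol = np.where(brain, bg_avg[f], 0.0)
        vol = np.where(tumour, tum_avg[f] * profile, vol)
        if noise_sigma > 0:
            vol = vol + rng.normal(0.0, noise_sigma, size=geo.shape)
        frames[f] = np.clip(vol, 0.0, None)
    series = DynamicPETSeries(frames, geo.spacing_mm, schema)

    # contralateral crescent reference region: a half-annulus on the -x
    # side of the central slices, inside the brain
    rho = np.sqrt(yc**2 + xc**2)
    crescent = (
        brain
        & ~tumour
        & (np.abs(zc) <= 4.0)
        & (xc <= -8.0)
        & (rho >= 14.0)
        & (rho <= 24.0)
    )
    if not crescent.any():
        raise GeometryError("reference crescent is empty for this geometry")
    reference = RegionMask(crescent, geo.spacing_mm)

    # ground-truth VOI curve: mean over the VOI sphere voxels around the
    # tumour centre voxel, with the parabolic profile and any background
    # voxels mixed in
    offsets = sphere_voxel_offsets(geo.spacing_mm, voi_radius_mm(voi_volume_ml))
    idx = offsets + np.asarray(geo.tumour_centre_index)
    inside = np.all((idx >= 0) & (idx < np.asarray(geo.shape)), axis=1)
    idx = idx[inside]
    zz, yy, xx = idx[:, 0], idx[:, 1], idx[:, 2]
    in_tum = tumour[zz, yy, xx]
    in_brain = brain[zz, yy, xx]
    n_voi = len(idx)
    tum_weight = profile[zz, yy, xx][in_tum].sum()
    n_bg = int((~in_tum & in_brain).sum())
    voi_tac = (tum_weight * tum_avg + n_bg * bg_avg) / n_voi

    ttp, peak = _discretized_ttp(schema.end_min, voi_tac)
    slope = _ols_slope_per_hour(schema.mid_min, voi_tac)
    truth = PhantomGroundTruth(
        kinetic_class=tumour_tac.kind,
        ttp_min=ttp,
        peak_identified=peak,
        slope_suv_per_h=slope,
        mtv_ml=geo.analytic_tumour_volume_ml,
        tumour_centre_index=geo.tumour_centre_index,
        continuous_peak_min=tumour_tac.peak_time_min,
        voi_tac=voi_tac,
        tumour_tac_model=asdict(tumour_tac),
    )
    return series, reference, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohortConfig:
    """Stated world of the synthetic survival cohort.

    Survival is class-conditional exponential: the late-peaking plateau
    class carries the favourable medians (OS 29 / PFS 13 months), the
    early-peaking washout class the unfavourable ones (OS 12 / PFS 7).
    Covariates are drawn independently and, by default, carry no hazard
    effect.  An MGMT promoter-methylation effect can be co-simulated by
    setting ``mgmt_hazard_ratio`` below 1: it multiplies the hazard with
    centred coding (sqrt(HR) down for methylated, up for unmethylated),
    preserving the class medians approximately marginally.  Censoring is
    administrative: a uniform follow-up horizon, calibrated to censor
    roughly 20% of patients for OS.
    """

    n_patients: int = 45
    proportion_washout: float = 0.5
    median_os_months: dict = field(
        default_factory=lambda: {"washout": 12.0, "plateau": 29.0}
    )
    median_pfs_months: dict = field(
        default_factory=lambda: {"washout": 7.0, "plateau": 13.0}
    )
    censoring_window_months: tuple[float, float] = (24.0, 84.0)
    mgmt_hazard_ratio: float = 1.0
    p_mgmt_methylated: float = 0.5
    p_idh_mutant: float = 0.0  # the default cohort emulates the IDH-wildtype subgroup
    p_kps_100: float = 0.45
    p_resection: dict = field(
        default_factory=lambda: {"biopsy": 0.35, "partial": 0.17, "complete": 0.48}
    )
    age_mean: float = 55.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (21.0, 78.0)
    p_who_grade_iv: float = 0.84
    noise_sigma: float = 0.05  # SUV, added to the per-patient TAC
    param_jitter: float = 0.12  # lognormal sd on the TAC model parameters
    tbr_max_by_class: dict = field(
        default_factory=lambda: {"washout": (3.1, 0.6), "plateau": (2.2, 0.5)}
    )
    tbr_mean_by_class: dict = field(
        default_factory=lambda: {"washout": (2.5, 0.4), "plateau": (1.8, 0.35)}
    )
    log_mtv_by_class: dict = field(
        default_factory=lambda: {
            "washout": (math.log(20.0), 0.5),
            "plateau": (math.log(8.0), 0.5),
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if not (0.0 <= self.proportion_washout <= 1.0):
            raise ValidationError("proportion_washout must be in [0, 1]")
        for d in (self.median_os_months, self.median_pfs_months):
            if set(d) != {"washout", "plateau"} or any(v <= 0 for v in d.values()):
                raise ValidationError(
                    "survival medians must be positive and keyed by "
                    "{'washout', 'plateau'}"
                )
        lo, hi = self.censoring_window_months
        if lo < 0 or hi < lo:
            raise ValidationError("censoring window must satisfy 0 <= lo <= hi")
        if self.seed is None:
            raise ValidationError("a seed is mandatory for reproducibility")


def _jittered_model(base: TACModel, rng, jitter: float) -> TACModel:
    def j(v, scale=1.0):
        return v * math.exp(rng.normal(0.0, jitter * scale))

    return TACModel(
        kind=base.kind,
        amplitude=j(base.amplitude),
        tau_up_min=j(base.tau_up_min),
        washout_per_min=0.0 if base.washout_per_min == 0 else j(
            base.washout_per_min, 1.5
        ),
        baseline=j(base.baseline),
    )


def generate_cohort(
    config: SyntheticCohortConfig, mode: str = "fast"
) -> tuple[list[PatientRecord], dict]:
    """Draw a cohort with known ground truth.

    ``fast`` mode derives per-patient TTP and slope from a jittered,
    noise-corrupted tabular TAC and draws the static parameters from
    class-conditional distributions.  ``image`` mode synthesizes a full
    phantom per patient and runs the complete image quantification
    (slow; intended for small n).
    """
    from .kinetics import compute_slope, compute_ttp, quantify_patient
    from .kinetics import TimeActivityCurve

    config.validate()
    if mode not in ("fast", "image"):
        raise ValidationError(f"mode must be 'fast' or 'image', got {mode!r}")
    rng = np.random.default_rng(config.seed)
    schema = default_frame_schema()
    records: list[PatientRecord] = []
    truth_rows: list[dict] = []

    res_levels = list(config.p_resection)
    res_probs = np.array([config.p_resection[k] for k in res_levels], dtype=float)
    res_probs = res_probs / res_probs.sum()

    for i in range(config.n_patients):
        cls = "washout" if rng.random() < config.proportion_washout else "plateau"
        base = WASHOUT_TAC if cls == "washout" else PLATEAU_TAC
        model = _jittered_model(base, rng, config.param_jitter)

        # covariates
        mgmt = "methylated" if rng.random() < config.p_mgmt_methylated else "unmethylated"
        idh = "mutant" if rng.random() < config.p_idh_mutant else "wildtype"
        kps = 100 if rng.random() < config.p_kps_100 else int(rng.choice([60, 70, 80, 90]))
        resection = str(rng.choice(res_levels, p=res_probs))
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                            *config.age_range))
        who = "IV" if rng.random() < config.p_who_grade_iv else "III"

        # survival: class-conditional exponential with a centred MGMT effect
        mgmt_factor = config.mgmt_hazard_ratio ** (0.5 if mgmt == "methylated" else -0.5)
        lam_os = math.log(2.0) / config.median_os_months[cls] * mgmt_factor
        lam_pfs = math.log(2.0) / config.median_pfs_months[cls] * mgmt_factor
        t_os = rng.exponential(1.0 / lam_os)
        t_pfs = min(rng.exponential(1.0 / lam_pfs), t_os)
        c = rng.uniform(*config.censoring_window_months)
        os_months, os_event = min(t_os, c), int(t_os <= c)
        pfs_months, pfs_event = min(t_pfs, c), int(t_pfs <= c)

        # PET parameters
        if mode == "image":
            series, ref_mask, ph_truth = generate_phantom(
                tumour_tac=model,
                noise_sigma=config.noise_sigma,
                seed=int(rng.integers(2**31 - 1)),
                schema=schema,
            )
            q = quantify_patient(series, ref_mask, include_reference_tac=False)
            tbr_mx, tbr_mn = q.static.tbr_max, q.static.tbr_mean
            mtv = q.static.mtv_ml
            ttp, slope = q.kinetic.ttp_min, q.kinetic.slope_suv_per_h
            true_ttp, true_slope = ph_truth.ttp_min, ph_truth.slope_suv_per_h
        else:
            noiseless = model.frame_averages(schema)
            noisy = np.clip(
                noiseless + rng.normal(0.0, config.noise_sigma, len(schema)),
                0.0,
                None,
            )
            tac = TimeActivityCurve(schema.mid_min, schema.end_min, noisy)
            ttp, _ = compute_ttp(tac)
            slope = compute_slope(tac)
            true_ttp, _ = _discretized_ttp(schema.end_min, noiseless)
            true_slope = _ols_slope_per_hour(schema.mid_min, noiseless)
            mu, sd = config.tbr_max_by_class[cls]
            tbr_mx = max(rng.normal(mu, sd), 1.0)
            mu, sd = config.tbr_mean_by_class[cls]
            tbr_mn = max(rng.normal(mu, sd), 1.0)
            mu, sd = config.log_mtv_by_class[cls]
            mtv = float(np.exp(rng.normal(mu, sd)))

        rec = PatientRecord(
            patient_id=f"SYN{i + 1:03d}",
            os_months=os_months,
            os_event=os_event,
            pfs_months=pfs_months,
            pfs_event=pfs_event,
            idh=idh,
            mgmt=mgmt,
            kps=kps,
            resection=resection,
            age_years=age,
            who_grade=who,
            tbr_max=float(tbr_mx),
            tbr_mean=float(tbr_mn),
            mtv_ml=float(mtv),
            ttp_min=float(ttp),
            slope_suv_per_h=float(slope),
        )
        rec.validate()
        records.append(rec)
        truth_rows.append(
            {
                "patient_id": rec.patient_id,
                "kinetic_class": cls,
                "true_ttp_min": true_ttp,
                "true_slope_suv_per_h": true_slope,
                "true_os_rate_per_month": lam_os,
                "true_pfs_rate_per_month": lam_pfs,
                "censor_time_months": c,
            }
        )

    ground_truth = {
        "config": asdict(config),
        "mode": mode,
        "patients": truth_rows,
    }
    return records, ground_truth
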