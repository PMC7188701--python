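# Methods

## Input model and units

All quantification operates on standardized uptake values
(SUV = tissue activity concentration / (injected dose / body weight)).
Raw Bq/mL data are converted once at ingest using the calibration sidecar;
decay correction is assumed to have been applied by the scanner.  Voxel
arrays are indexed `(frame, z, y, x)` with spacing `(dz, dy, dx)` in mm.
Masks must live on the identical grid; no resampling is performed, which
keeps every geometric operation bit-exact and testable.  The default frame
schema is the 16-frame 0–50 min acquisition (5 × 1, 5 × 3, 6 × 5 min);
any contiguous schema starting at 0 is accepted.  An optional isotropic
Gaussian pre-smoothing (mm FWHM) is exposed for cross-scanner
harmonization experiments but defaults to off.

## Static parameters

* **Evaluation image** — duration-weighted mean SUV of all frames fully
  inside the 20–40 min window (equal weights for the default schema's four
  5-min frames).  The window must align with frame boundaries; misaligned
  requests fail with the available boundaries listed.
* **Reference** — arithmetic mean SUV over a user-supplied healthy-brain
  mask (typically a contralateral crescent in the centrum semiovale).
  Automatic reference placement is deliberately out of scope: in practice
  that ROI is drawn and validated by experts, and no algorithmic
  definition would be faithful.
* **Hottest voxel** — global (or search-mask-restricted) maximum of the
  evaluation image; ties break to the lowest `(z, y, x)` index so results
  are deterministic.
* **TBRmax** — mean SUV over the in-plane disc of diameter 16 mm centred
  on the hottest voxel, divided by the reference mean.  Membership is by
  voxel-centre distance in physical mm (correct under anisotropic in-plane
  spacing); a disc clipped by the image border degrades to the interior
  part with a warning.  Using the disc mean (not the single hottest voxel)
  follows the convention of dividing tumour *ROI mean* SUV by brain mean.
* **TBRmean** — mean SUV over the 4-connected component of
  `SUV ≥ 1.6 × reference` containing the hottest voxel, in that voxel's
  transversal slice, divided by the reference mean.
* **MTV** — volume of the 6-connected 3D component of
  `SUV ≥ 1.6 × reference` containing the hottest voxel
  (`voxel count × voxel volume`).  Seeding the component at the hottest
  voxel, rather than taking all supra-threshold voxels, is a design
  choice: an auto-contour is a single closed region around the lesion, and
  disconnected supra-threshold tissue must not inflate the volume.  If
  even the hottest voxel is below threshold, `tumour_detected` is false,
  MTV is 0 and TBRmean is NaN.

All static parameters are invariant under global intensity rescaling, and
the MTV mask grows monotonically as the threshold drops (both are property
tests).

## Kinetic parameters

* **TAC** — frame-wise mean SUV over a 2 mL sphere
  (r = (3V/4π)^(1/3) ≈ 7.816 mm) centred on the hottest voxel of the
  evaluation image (not a per-frame maximum), membership by voxel-centre
  distance.
* **TTP** — frame *end* time of the earliest frame attaining the global
  TAC maximum.  "No identifiable peak" is operationalized as: that frame
  is the final frame; then TTP is the acquisition end (50 min) and
  `peak_identified` is false.  Any softer peak-prominence rule would
  introduce unstated parameters.  A frame *mid*-time convention is
  available behind a flag for sensitivity analysis.  A constant TAC
  resolves to the first frame with a warning.
* **Slope** — OLS slope of mean SUV against frame mid-time over frames
  whose mid-time lies in 20–50 min (the default schema contributes exactly
  the six 5-min frames, mid-times 22.5 … 47.5 min), × 60 to give SUV/h.
  Mid-times are the standard abscissae for frame-averaged activity.

TTP is invariant under positive rescaling and constant shifts of the TAC;
slope is shift-invariant and scales linearly — both are property tests.

## Survival analysis

* **Favourable-OS label** — favourable if OS ≥ 24 months regardless of
  vital status; unfavourable if death before 24 months; patients censored
  alive before 24 months are *indeterminate* and excluded from ROC, with
  the exclusion count reported.  Treating them as unfavourable would bias
  against long-censored survivors.
* **ROC** — empirical AUC by rank/pair counting (ties ½), auto-oriented so
  AUC ≥ 0.5 with the orientation reported (`higher_favourable` /
  `lower_favourable`).  Candidate cutoffs are midpoints of consecutive
  distinct values; the optimum maximizes sensitivity × specificity, ties
  broken toward higher specificity.  SE by the Hanley–McNeil two-sample
  formula; p-value from a two-sided z-test of AUC against 0.5.
  Note that no data-processing inequality holds between the continuous and
  the dichotomized empirical AUC: the binarized AUC equals
  (sens + spec)/2, the trapezoid through the chosen ROC point, which can
  exceed the area under a non-concave empirical curve.
* **Kaplan–Meier / log-rank** — product-limit estimation and the two-group
  log-rank test via lifelines.  The reported median is the earliest time
  the survival curve drops *strictly below* 0.5 (so an uncensored sample
  {2, 4, 6, 8} has median 6), NaN when never reached.
* **Cox model** — partial likelihood with Efron tie handling (lifelines).
  Factors enter the multivariate stage when their OS log-rank p < 0.05.
  TTP and MTV are coded continuously (hazard ratios per minute / per mL);
  all other factors as indicators at their thresholds (clinical cuts:
  age ≥ 70, KPS = 100, complete resection, IDH mutant, MGMT methylated;
  PET cuts: the ROC-derived or user-overridden thresholds).  Constant
  covariates and non-convergence (e.g. complete separation) raise
  structured errors; an events-per-covariate ratio below 10 warns.
* **Subgroup** — the analysis defaults to the IDH-wildtype subgroup (the
  setting in which kinetic parameters are reported to carry independent
  prognostic value); configurable, including no filter.

## Synthetic world

The phantom is phenomenological, not physical: a brain-shaped ellipsoid
with slowly rising background uptake (late value ≈ 1.1 SUV), a spherical
tumour (default radius 10 mm) on one side, and a contralateral half-annulus
crescent as the reference region.  Tissue curves follow
`u(t) = b + A(1 − e^(−t/τ)) e^(−wt)`; the washout class
(A = 3, τ = 4 min, w = 0.02/min, b = 0.5 ⇒ continuous peak ≈ 10 min,
late slope ≈ −1.9 SUV/h) emulates aggressive early-peak kinetics, the
plateau class (A = 2.5, τ = 12 min, w = 0) steadily increasing uptake.
Frame values are the *exact* analytic time-average of `u` over each frame
interval — point-sampling would hide frame-time convention bugs — plus
i.i.d. Gaussian noise truncated at zero (σ configurable; lognormal noise
was rejected as needlessly parameterized).  A mild parabolic uptake
profile inside the tumour (+10% at the centre) makes the hottest voxel
unique and central; the ground-truth VOI curve accounts for that profile
and for any background voxels inside the VOI sphere, so noiseless
pipeline output equals ground truth to machine precision.  Ground-truth
TTP/slope are computed by generator-local closed forms, independent of
the quantifier's code paths.

Cohorts tie survival to the kinetic class: exponential OS/PFS with
medians 29/13 months (plateau = late TTP, favourable) versus 12/7 months
(washout = early TTP, unfavourable), administrative uniform censoring over
24–84 months of follow-up (≈ 19–20% censored for OS), covariates drawn
independently with realistic frequencies (half MGMT-methylated, ~84% WHO
grade IV, age ≈ N(55, 12) clipped to 21–78; the default cohort is all
IDH-wildtype, emulating the analysis subgroup).  Covariates carry no
hazard effect by default; an MGMT effect (hazard ratio 0.45, from the
reported ≈ 29 vs 12 month OS separation by methylation status) can be
co-simulated, applied with centred coding (√HR down for methylated, up
for unmethylated) so the class-conditional medians stay approximately
calibrated marginally.  Fast mode draws TTP/slope from jittered,
noise-corrupted tabular TACs and the static parameters from
class-conditional distributions; image mode synthesizes a full phantom
per patient and runs the complete image pipeline.

What a green synthetic test does *not* establish: robustness to real PET
physics (partial volume, scatter, reconstruction artefacts, motion),
anatomical heterogeneity, non-exponential survival, informative
censoring, or correlated covariates.  The measured log-rank power of the
calibrated 45-patient world (~0.80 over 200 replicates) sits at the edge
of its own acceptance bound — the Schoenfeld approximation with ~36
events and log HR ≈ 0.88 predicts 0.75–0.80 — so that check is expected
to be tight.

## Numerical and convention choices

* Ties at the image maximum, at the TAC maximum, and in the ROC cutoff
  product are all broken deterministically (lexicographic index, earlier
  frame, higher specificity).
* All randomness flows through one `numpy` `default_rng` seeded generator
  per entry point; identical seeds give bit-identical phantoms, cohorts
  and reports.
* Cox convergence is flagged via lifelines' convergence warnings
  (gradient-based stopping inside lifelines); degenerate designs raise
  before fitting.
* Survival times are kept continuous (months); no rounding is applied.
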