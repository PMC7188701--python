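"""ROC threshold derivation and survival statistics for PET parameters.

The analysis mirrors a standard imaging-biomarker workflow:

1. Each PET parameter is scored against a binary "favourable overall
   survival" label (OS >= 24 months) by ROC analysis; the optimal decision
   cutoff maximizes the product of sensitivity and specificity.
2. Each parameter, dichotomized at its cutoff, and the clinical factors at
   their conventional cuts are tested univariately with Kaplan-Meier
   estimates and the log-rank test, for PFS and OS.
3. Factors univariately significant for OS enter a multivariate Cox
   proportional-hazards model (Efron tie handling).

Kaplan-Meier fitting, the log-rank test and the Cox partial likelihood are
delegated to lifelines; the ROC construction, the sens x spec cutoff rule
and the Hanley-McNeil AUC standard error are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test

from .cohort import PET_PARAMETERS, PatientRecord
from .errors import AnalysisError, StageError, ValidationError

__all__ = [
    "ROCResult",
    "KMResult",
    "CoxResult",
    "CovariateSpec",
    "AnalysisConfig",
    "SurvivalReport",
    "favourable_os_label",
    "roc_optimal_cutoff",
    "km_logrank",
    "km_median",
    "cox_fit",
    "cox_fit_frame",
    "run_survival_analysis",
]

DEFAULT_FAVOURABLE_OS_MONTHS = 24.0


# ---------------------------------------------------------------------------
# favourable-OS reference label
# ---------------------------------------------------------------------------


def favourable_os_label(
    record: PatientRecord, cutoff_months: float = DEFAULT_FAVOURABLE_OS_MONTHS
) -> str:
    """Classify a patient against the favourable-OS reference.

    ``favourable`` if OS reached the cutoff (regardless of vital status),
    ``unfavourable`` if the patient died before it, and ``indeterminate``
    if censored alive before the cutoff — such patients cannot be assigned
    a class and are excluded from ROC analysis.
    """
    if record.os_months >= cutoff_months:
        return "favourable"
    if record.os_event == 1:
        return "unfavourable"
    return "indeterminate"


# ---------------------------------------------------------------------------
# ROC analysis with the sens x spec optimal cutoff
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    """Empirical ROC summary for one parameter against the favourable label."""

    auc: float
    auc_se: float
    threshold: float
    sensitivity: float
    specificity: float
    direction: str  # higher_favourable | lower_favourable
    n_pos: int
    n_neg: int
    n_excluded: int = 0
    p_value: float = math.nan

    def __post_init__(self):
        if not math.isnan(self.auc) and not (0.0 <= self.auc <= 1.0):
            raise ValidationError(f"AUC out of [0, 1]: {self.auc}")


def _auc_rank(values: np.ndarray, positive: np.ndarray) -> float:
    """Empirical AUC by the rank (Mann-Whitney) construction, ties count 1/2."""
    from scipy.stats import rankdata

    ranks = rankdata(values)
    n_pos = int(positive.sum())
    n_neg = len(values) - n_pos
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u) / (n_pos * n_neg)


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def roc_optimal_cutoff(
    values, labels, n_excluded: int = 0
) -> ROCResult:
    """ROC analysis of one parameter against favourable/unfavourable labels.

    The AUC is the empirical pair-counting probability (ties contribute
    1/2), auto-oriented so that AUC >= 0.5 with the orientation recorded in
    ``direction``.  Candidate cutoffs are midpoints between consecutive
    distinct values; the returned cutoff maximizes sensitivity x
    specificity, with ties broken toward higher specificity.  The AUC
    standard error uses the Hanley-McNeil two-sample formula, and the
    p-value is a two-sided z-test of AUC against 0.5.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        bad = set(labels) - {"favourable", "unfavourable"}
        if bad:
            raise ValidationError(f"unknown ROC labels: {sorted(bad)}")
        positive = labels == "favourable"
    else:
        positive = labels.astype(bool)
    if len(values) != len(positive):
        raise ValidationError("values and labels differ in length")
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise AnalysisError(
            f"ROC needs both classes represented (favourable={n_pos}, "
            f"unfavourable={n_neg})"
        )

    auc = _auc_rank(values, positive)
    direction = "higher_favourable"
    if auc < 0.5:
        direction = "lower_favourable"
        auc = 1.0 - auc

    distinct = np.unique(values)
    if len(distinct) == 1:
        warnings.warn(
            "all parameter values identical: AUC 0.5, no cutoff", stacklevel=2
        )
        return ROCResult(
            auc=0.5,
            auc_se=hanley_mcneil_se(0.5, n_pos, n_neg),
            threshold=math.nan,
            sensitivity=math.nan,
            specificity=math.nan,
            direction=direction,
            n_pos=n_pos,
            n_neg=n_neg,
            n_excluded=n_excluded,
            p_value=1.0,
        )

    cutpoints = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for c in cutpoints:
        if direction == "higher_favourable":
            predicted_fav = values > c
        else:
            predicted_fav = values < c
        sens = float(predicted_fav[positive].mean())
        spec = float((~predicted_fav[~positive]).mean())
        key = (sens * spec, spec)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, threshold, sens, spec = best

    se = hanley_mcneil_se(auc, n_pos, n_neg)
    if se > 0:
        from scipy.stats import norm

        p = float(2.0 * norm.sf(abs(auc - 0.5) / se))
    else:
        p = math.nan
    return ROCResult(
        auc=auc,
        auc_se=se,
        threshold=float(threshold),
        sensitivity=sens,
        specificity=spec,
        direction=direction,
        n_pos=n_pos,
        n_neg=n_neg,
        n_excluded=n_excluded,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def km_median(times, events) -> float:
    """Median survival: earliest time the KM curve drops strictly below 0.5.

    NaN when the curve never falls below 0.5 (median not reached).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    sf = kmf.survival_function_.iloc[:, 0]
    below = sf[sf < 0.5]
    if len(below) == 0:
        return math.nan
    return float(below.index[0])


@dataclass
class KMResult:
    """Two-group Kaplan-Meier comparison with the log-rank test."""

    group_labels: tuple[str, ...]
    n: tuple[int, ...]
    n_events: tuple[int, ...]
    median_months: tuple[float, ...]
    logrank_chi2: float
    p_value: float
    curves: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)


def km_logrank(times, events, groups, group_labels=None) -> KMResult:
    """Product-limit estimates per group and the two-group log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise AnalysisError(
            f"log-rank comparison needs exactly 2 non-empty groups, got "
            f"{len(uniq)}"
        )
    if events.sum() == 0:
        raise AnalysisError("no events observed; log-rank test undefined")
    if group_labels is None:
        group_labels = tuple(str(u) for u in uniq)

    ns, n_ev, medians, curves = [], [], [], {}
    for u, lbl in zip(uniq, group_labels):
        sel = groups == u
        ns.append(int(sel.sum()))
        n_ev.append(int(events[sel].sum()))
        medians.append(km_median(times[sel], events[sel]))
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=lbl)
        curves[lbl] = kmf.survival_function_.reset_index().set_axis(
            ["time_months", "survival"], axis=1
        )

    res = multivariate_logrank_test(times, groups, events)
    return KMResult(
        group_labels=tuple(group_labels),
        n=tuple(ns),
        n_events=tuple(n_ev),
        median_months=tuple(medians),
        logrank_chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        curves=curves,
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CovariateSpec:
    """How one covariate enters the Cox model.

    ``coding`` is ``continuous`` (raw value) or ``binary`` (indicator).
    Binary numeric covariates use ``value >= threshold``; binary categorical
    covariates use ``value == positive_level``.
    """

    name: str
    coding: str = "continuous"
    threshold: float | None = None
    positive_level: str | None = None

    def __post_init__(self):
        if self.coding not in ("continuous", "binary"):
            raise ValidationError(f"unknown coding {self.coding!r}")
        if self.coding == "binary" and (
            self.threshold is None and self.positive_level is None
        ):
            raise ValidationError(
                f"binary coding of {self.name!r} needs a threshold or a "
                f"positive_level"
            )

    @property
    def column(self) -> str:
        if self.coding == "continuous":
            return self.name
        if self.positive_level is not None:
            return f"{self.name}={self.positive_level}"
        return f"{self.name}>={self.threshold:g}"

    def encode(self, record: PatientRecord) -> float:
        value = getattr(record, self.name)
        if self.coding == "continuous":
            return float(value)
        if self.positive_level is not None:
            return float(value == self.positive_level)
        return float(float(value) >= self.threshold)


@dataclass
class CoxResult:
    """Multivariate Cox fit: per-covariate estimates and diagnostics.

    ``table`` is indexed by covariate column with columns
    beta, hazard_ratio, ci95_low, ci95_high, p_value.
    """

    table: pd.DataFrame
    n: int
    n_events: int
    converged: bool


def cox_fit_frame(
    df: pd.DataFrame, duration_col: str, event_col: str, covariate_cols
) -> CoxResult:
    """Fit a Cox model (Efron ties) on an arbitrary prepared DataFrame."""
    covariate_cols = list(covariate_cols)
    n_events = int(df[event_col].sum())
    if n_events < len(covariate_cols):
        raise AnalysisError(
            f"{n_events} events cannot support {len(covariate_cols)} covariates"
        )
    if n_events < 10 * len(covariate_cols):
        warnings.warn(
            f"events-per-covariate {n_events / len(covariate_cols):.1f} < 10; "
            f"estimates may be unstable",
            stacklevel=2,
        )
    for col in covariate_cols:
        if df[col].nunique() < 2:
            raise AnalysisError(
                f"covariate {col!r} is constant across patients; remove it "
                f"from the model"
            )

    cph = CoxPHFitter()
    converged = True
    fit_df = df[[duration_col, event_col] + covariate_cols]
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(fit_df, duration_col=duration_col, event_col=event_col)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    except ConvergenceError as exc:
        raise AnalysisError(
            f"Cox model failed to converge (possible complete separation); "
            f"consider removing a covariate: {exc}"
        ) from exc

    summary = cph.summary
    table = pd.DataFrame(
        {
            "beta": summary["coef"],
            "hazard_ratio": summary["exp(coef)"],
            "ci95_low": summary["exp(coef) lower 95%"],
            "ci95_high": summary["exp(coef) upper 95%"],
            "p_value": summary["p"],
        }
    )
    table.index.name = "covariate"
    return CoxResult(table=table, n=len(df), n_events=n_events, converged=converged)


def cox_fit(
    records: list[PatientRecord],
    covariates: list[CovariateSpec],
    endpoint: str = "os",
) -> CoxResult:
    """Fit the multivariate Cox model on a cohort for the given endpoint."""
    if endpoint not in ("os", "pfs"):
        raise ValidationError(f"endpoint must be 'os' or 'pfs', got {endpoint!r}")
    rows = {
        "duration": [getattr(r, f"{endpoint}_months") for r in records],
        "event": [getattr(r, f"{endpoint}_event") for r in records],
    }
    for spec in covariates:
        rows[spec.column] = [spec.encode(r) for r in records]
    df = pd.DataFrame(rows)
    return cox_fit_frame(df, "duration", "event", [s.column for s in covariates])


# ---------------------------------------------------------------------------
# orchestration: ROC -> univariate KM/log-rank -> multivariate Cox
# ---------------------------------------------------------------------------

#: clinical factors at their conventional cuts (label, spec, description)
DEFAULT_CLINICAL_FACTORS: tuple[CovariateSpec, ...] = (
    CovariateSpec("age_years", "binary", threshold=70.0),
    CovariateSpec("resection", "binary", positive_level="complete"),
    CovariateSpec("idh", "binary", positive_level="mutant"),
    CovariateSpec("mgmt", "binary", positive_level="methylated"),
    CovariateSpec("kps", "binary", threshold=100.0),
)

#: Cox coding of PET parameters: TTP and MTV enter continuously, the rest
#: dichotomized at their derived thresholds
CONTINUOUS_IN_COX = ("ttp_min", "mtv_ml")


@dataclass
class AnalysisConfig:
    """Configuration of the full survival analysis."""

    favourable_os_cutoff_months: float = DEFAULT_FAVOURABLE_OS_MONTHS
    subgroup: dict = field(default_factory=lambda: {"idh": "wildtype"})
    pet_parameters: tuple[str, ...] = PET_PARAMETERS
    threshold_overrides: dict = field(default_factory=dict)
    alpha: float = 0.05
    clinical_factors: tuple[CovariateSpec, ...] = DEFAULT_CLINICAL_FACTORS

    def to_dict(self) -> dict:
        return {
            "favourable_os_cutoff_months": self.favourable_os_cutoff_months,
            "subgroup": dict(self.subgroup),
            "pet_parameters": list(self.pet_parameters),
            "threshold_overrides": dict(self.threshold_overrides),
            "alpha": self.alpha,
            "clinical_factors": [
                {
                    "name": s.name,
                    "coding": s.coding,
                    "threshold": s.threshold,
                    "positive_level": s.positive_level,
                }
                for s in self.clinical_factors
            ],
        }


@dataclass
class SurvivalReport:
    """Machine-readable analysis report (ROC, univariate, Cox tables)."""

    n_analysed: int
    roc_table: pd.DataFrame
    univariate_table: pd.DataFrame
    cox: CoxResult | None
    cox_covariates: tuple[str, ...]
    thresholds: dict
    km_results: dict = field(default_factory=dict, repr=False)
    notes: list = field(default_factory=list)
    config: dict = field(default_factory=dict)


def _apply_subgroup(
    records: list[PatientRecord], subgroup: dict
) -> list[PatientRecord]:
    out = records
    for key, level in (subgroup or {}).items():
        out = [r for r in out if getattr(r, key) == level]
    return out


def run_survival_analysis(
    cohort: list[PatientRecord], config: AnalysisConfig | None = None
) -> SurvivalReport:
    """ROC thresholds, univariate KM/log-rank, and the multivariate Cox model.

    Stage errors are re-raised with the stage name attached.
    """
    config = config or AnalysisConfig()
    records = _apply_subgroup(cohort, config.subgroup)
    if not records:
        raise AnalysisError(f"subgroup filter {config.subgroup} leaves no patients")
    notes: list[str] = []

    # --- stage 1: ROC per PET parameter -----------------------------------
    roc_rows, thresholds, roc_results = [], {}, {}
    for param in config.pet_parameters:
        labels, values = [], []
        n_excluded = 0
        for r in records:
            v = getattr(r, param)
            lbl = favourable_os_label(r, config.favourable_os_cutoff_months)
            if lbl == "indeterminate" or not np.isfinite(v):
                n_excluded += 1
                continue
            labels.append(lbl)
            values.append(v)
        try:
            roc = roc_optimal_cutoff(values, labels, n_excluded=n_excluded)
        except (AnalysisError, ValidationError) as exc:
            raise StageError(f"roc:{param}", exc) from exc
        roc_results[param] = roc
        threshold = config.threshold_overrides.get(param, roc.threshold)
        if param in config.threshold_overrides:
            notes.append(
                f"{param}: ROC-derived cutoff {roc.threshold:.4g} overridden "
                f"by configured {threshold:.4g}"
            )
        thresholds[param] = threshold
        roc_rows.append(
            {
                "parameter": param,
                "threshold": threshold,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "auc": roc.auc,
                "auc_se": roc.auc_se,
                "p_value": roc.p_value,
                "direction": roc.direction,
                "n_favourable": roc.n_pos,
                "n_unfavourable": roc.n_neg,
                "n_excluded": roc.n_excluded,
            }
        )
    roc_table = pd.DataFrame(roc_rows)

    # --- stage 2: univariate KM / log-rank for PFS and OS ------------------
    factors: list[CovariateSpec] = list(config.clinical_factors)
    for param in config.pet_parameters:
        factors.append(
            CovariateSpec(param, "binary", threshold=thresholds[param])
        )

    uni_rows, km_results = [], {}
    os_significant: list[CovariateSpec] = []
    for spec in factors:
        indicators = np.array([spec.encode(r) for r in records])
        if len(np.unique(indicators)) < 2:
            notes.append(
                f"univariate: factor {spec.column} is constant in the "
                f"analysed subgroup; skipped"
            )
            continue
        row = {"factor": spec.name, "criterion": spec.column}
        for endpoint in ("pfs", "os"):
            times = np.array([getattr(r, f"{endpoint}_months") for r in records])
            events = np.array([getattr(r, f"{endpoint}_event") for r in records])
            try:
                km = km_logrank(
                    times,
                    events,
                    indicators,
                    group_labels=(f"not {spec.column}", spec.column),
                )
            except AnalysisError as exc:
                raise StageError(f"km:{spec.column}:{endpoint}", exc) from exc
            km_results[(spec.column, endpoint)] = km
            row[f"{endpoint}_p"] = km.p_value
            row[f"{endpoint}_median_group0"] = km.median_months[0]
            row[f"{endpoint}_median_group1"] = km.median_months[1]
        uni_rows.append(row)
        if row["os_p"] < config.alpha:
            os_significant.append(spec)
    univariate_table = pd.DataFrame(uni_rows)

    # --- stage 3: multivariate Cox on univariate-significant factors -------
    cox_specs: list[CovariateSpec] = []
    for spec in os_significant:
        if spec.name in CONTINUOUS_IN_COX:
            cox_specs.append(CovariateSpec(spec.name, "continuous"))
        else:
            cox_specs.append(spec)
    cox_result = None
    if cox_specs:
        try:
            cox_result = cox_fit(records, cox_specs, endpoint="os")
        except AnalysisError as exc:
            raise StageError("cox", exc) from exc
    else:
        notes.append(
            "no factor reached univariate significance for OS; Cox stage "
            "skipped"
        )

    return SurvivalReport(
        n_analysed=len(records),
        roc_table=roc_table,
        univariate_table=univariate_table,
        cox=cox_result,
        cox_covariates=tuple(s.column for s in cox_specs),
        thresholds=thresholds,
        km_results=km_results,
        notes=notes,
        config=config.to_dict(),
    )
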