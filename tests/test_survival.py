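"""ROC cutoffs, Kaplan-Meier/log-rank, and Cox proportional hazards."""

import numpy as np
import pandas as pd
import pytest

from dynfet import (
    AnalysisError,
    CovariateSpec,
    SyntheticCohortConfig,
    cox_fit,
    favourable_os_label,
    generate_cohort,
    km_logrank,
    km_median,
    roc_optimal_cutoff,
    run_survival_analysis,
)
from dynfet.cohort import PatientRecord
from dynfet.errors import StageError
from dynfet.survival import AnalysisConfig, cox_fit_frame, hanley_mcneil_se


def brute_force_auc(values, positive):
    """Pair-counting oracle: P(pos > neg) + 1/2 P(pos == neg)."""
    values = np.asarray(values, float)
    pos = values[np.asarray(positive, bool)]
    neg = values[~np.asarray(positive, bool)]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def record(os_months, os_event, **kw):
    defaults = dict(
        patient_id="P", pfs_months=min(os_months, 5.0), pfs_event=1,
        idh="wildtype", mgmt="methylated", kps=90, resection="complete",
        age_years=55.0, who_grade="IV",
    )
    defaults.update(kw)
    return PatientRecord(os_months=os_months, os_event=os_event, **defaults)


class TestFavourableLabel:
    @pytest.mark.parametrize(
        "os_months,os_event,expected",
        [
            (29, 1, "favourable"),   # reached the cutoff, death irrelevant
            (25, 0, "favourable"),   # censored after the cutoff
            (12, 1, "unfavourable"),
            (10, 0, "indeterminate"),  # censored alive before 24 months
        ],
    )
    def test_label(self, os_months, os_event, expected):
        assert favourable_os_label(record(os_months, os_event)) == expected


class TestRocOptimalCutoff:
    def test_perfect_separation(self):
        r = roc_optimal_cutoff(
            [1, 2, 3, 4],
            ["unfavourable", "unfavourable", "favourable", "favourable"],
        )
        assert r.auc == 1.0
        assert 2 < r.threshold < 3
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.direction == "higher_favourable"

    def test_interleaved_labels_match_pair_counting(self):
        # oracle: fav values {1, 3} vs unfav {2, 4} -> 1/4 of pairs won,
        # 0.75 after orientation
        values = [1, 2, 3, 4]
        positive = [True, False, True, False]
        assert brute_force_auc(values, positive) == 0.25
        r = roc_optimal_cutoff(values, np.array(positive))
        assert r.auc == pytest.approx(0.75)
        assert r.direction == "lower_favourable"

    def test_tied_value_contributes_half(self):
        # fav {1, 2}, unfav {2, 3}: pairs (1,2)=0 (1,3)=0 (2,2)=1/2 (2,3)=0
        values = [1, 2, 2, 3]
        positive = [True, True, False, False]
        assert brute_force_auc(values, positive) == 0.125
        r = roc_optimal_cutoff(values, np.array(positive))
        assert r.auc == pytest.approx(0.875)

    def test_rank_auc_equals_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 51)
            values = rng.choice(rng.uniform(-5, 5, max(2, n // 2)), size=n)
            positive = rng.random(n) < 0.5
            if positive.all() or not positive.any():
                continue
            r = roc_optimal_cutoff(values, positive)
            oracle = brute_force_auc(values, positive)
            assert r.auc == pytest.approx(max(oracle, 1 - oracle), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0, 2, 40)
        positive = rng.random(40) < 0.5
        r0 = roc_optimal_cutoff(values, positive)
        for f in (np.exp, lambda v: v**3, lambda v: 10 + 0.1 * v):
            r = roc_optimal_cutoff(f(values), positive)
            assert r.auc == pytest.approx(r0.auc, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError, match="both classes"):
            roc_optimal_cutoff([1, 2], np.array([True, True]))

    def test_identical_values_warn_auc_half(self):
        with pytest.warns(UserWarning, match="identical"):
            r = roc_optimal_cutoff([2, 2, 2], np.array([True, False, True]))
        assert r.auc == 0.5 and np.isnan(r.threshold)

    def test_hanley_mcneil_agrees_with_formula(self):
        auc, n_pos, n_neg = 0.9, 10, 15
        q1, q2 = auc / (2 - auc), 2 * auc**2 / (1 + auc)
        var = (auc * (1 - auc) + 9 * (q1 - auc**2) + 14 * (q2 - auc**2)) / 150
        assert hanley_mcneil_se(auc, n_pos, n_neg) == pytest.approx(np.sqrt(var))

    def test_auc_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        values = rng.normal(size=60) + rng.integers(0, 2, 60)
        positive = rng.random(60) < 0.5
        if positive.all() or not positive.any():
            pytest.skip("degenerate draw")
        r = roc_optimal_cutoff(values, positive)
        sk = roc_auc_score(positive.astype(int), values)
        assert r.auc == pytest.approx(max(sk, 1 - sk), abs=1e-12)

    def test_binarized_auc_is_mean_of_sens_and_spec(self):
        # dichotomizing at a cutoff collapses the ROC curve to one point;
        # the empirical AUC of the binarized variable is exactly
        # (sens + spec) / 2 at that point (the trapezoid through it) —
        # which may exceed the area under a non-concave empirical curve,
        # so no data-processing inequality holds for raw empirical AUCs
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(50):
            values = rng.normal(size=30) + 0.8 * (rng.random(30) < 0.5)
            positive = rng.random(30) < 0.5
            if positive.all() or not positive.any():
                continue
            r = roc_optimal_cutoff(values, positive)
            if np.isnan(r.threshold):
                continue
            if r.direction == "higher_favourable":
                binary = (values > r.threshold).astype(float)
            else:
                binary = (values < r.threshold).astype(float)
            if len(np.unique(binary)) < 2:
                continue
            rb = roc_optimal_cutoff(binary, positive)
            assert rb.auc == pytest.approx(
                (r.sensitivity + r.specificity) / 2.0, abs=1e-12
            )
            checked += 1
        assert checked > 30


class TestKaplanMeier:
    def test_median_of_even_uncensored_sample(self):
        # S drops to 0.5 at t=4 and below 0.5 at t=6; the step convention
        # reports the first time strictly below one half
        assert km_median([2, 4, 6, 8], [1, 1, 1, 1]) == 6.0

    def test_median_not_reached_is_nan(self):
        assert np.isnan(km_median([5, 10, 15, 20], [1, 0, 0, 0]))

    def test_exponential_median_within_10pct(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(15.0 / np.log(2.0), 1000)
        assert km_median(t, np.ones(1000)) == pytest.approx(15.0, rel=0.10)

    def test_identical_groups_give_chi2_zero(self):
        times = [3, 6, 9, 12, 15]
        events = [1, 1, 0, 1, 0]
        km = km_logrank(times * 2, events * 2, [0] * 5 + [1] * 5)
        assert km.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert km.p_value == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(AnalysisError, match="2"):
            km_logrank([1, 2, 3], [1, 1, 1], [0, 0, 0])

    def test_no_events_rejected(self):
        with pytest.raises(AnalysisError, match="events"):
            km_logrank([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(5)
        t0 = rng.exponential(10, 40)
        t1 = rng.exponential(40, 40)
        km = km_logrank(
            np.concatenate([t0, t1]), np.ones(80), [0] * 40 + [1] * 40
        )
        assert km.p_value < 1e-4
        assert km.median_months[1] > km.median_months[0]


class TestCox:
    def test_binary_covariate_recovers_hazard_ratio_2(self):
        # two large exponential arms with a true hazard ratio of 2; the
        # mean estimate over replicates must land in [1.8, 2.2]
        rng = np.random.default_rng(6)
        n = 500
        hrs = []
        for _ in range(10):
            t0 = rng.exponential(20.0, n)       # baseline arm
            t1 = rng.exponential(10.0, n)       # hazard doubled
            df = pd.DataFrame(
                {
                    "d": np.concatenate([t0, t1]),
                    "e": np.ones(2 * n, int),
                    "x": np.r_[np.zeros(n), np.ones(n)],
                }
            )
            res = cox_fit_frame(df, "d", "e", ["x"])
            assert res.converged
            hrs.append(res.table.loc["x", "hazard_ratio"])
        assert 1.8 <= np.mean(hrs) <= 2.2

    def test_constant_covariate_rejected(self):
        recs = [record(10 + i, 1) for i in range(30)]
        with pytest.raises(AnalysisError, match="constant"):
            cox_fit(recs, [CovariateSpec("idh", "binary", positive_level="mutant")])

    def test_null_covariate_p_uniform_smoke(self):
        # 200-cohort smoke version of the type-I error check
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "d": rng.exponential(15.0, 60),
                    "e": np.ones(60, int),
                    "x": rng.normal(size=60),
                }
            )
            res = cox_fit_frame(df, "d", "e", ["x"])
            rejections += res.table.loc["x", "p_value"] < 0.05
        # binomial(200, 0.05): 3 sigma band
        assert abs(rejections / 200 - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)

    def test_events_per_covariate_warning(self):
        recs = [
            record(5 + i, 1, mgmt="methylated" if i % 2 else "unmethylated")
            for i in range(8)
        ]
        with pytest.warns(UserWarning, match="events-per-covariate"):
            cox_fit(recs, [CovariateSpec("mgmt", "binary",
                                         positive_level="methylated")])


class TestRunSurvivalAnalysis:
    def test_strong_ttp_effect_reaches_cox_stage(self):
        records, _ = generate_cohort(SyntheticCohortConfig(seed=1))
        report = run_survival_analysis(records)
        assert report.n_analysed == len(records)
        assert "ttp_min" in report.cox_covariates
        assert set(report.roc_table["parameter"]) == {
            "tbr_max", "tbr_mean", "mtv_ml", "ttp_min", "slope_suv_per_h"
        }

    def test_ttp_and_mtv_enter_cox_continuously(self):
        records, _ = generate_cohort(SyntheticCohortConfig(seed=1))
        report = run_survival_analysis(records)
        for cov in report.cox_covariates:
            if cov.startswith(("ttp_min", "mtv_ml")):
                assert ">=" not in cov  # continuous coding, no threshold

    def test_null_cohort_skips_cox_with_note(self):
        # survival independent of every parameter: no factor should
        # (usually) reach significance for this seed
        rng = np.random.default_rng(12)
        recs = []
        for i in range(40):
            t = rng.exponential(15.0)
            recs.append(
                record(
                    t, 1, patient_id=f"P{i}",
                    mgmt="methylated" if rng.random() < 0.5 else "unmethylated",
                    tbr_max=rng.normal(2.5, 0.5), tbr_mean=rng.normal(2.0, 0.4),
                    mtv_ml=rng.uniform(1, 30), ttp_min=rng.uniform(5, 50),
                    slope_suv_per_h=rng.normal(0, 1),
                )
            )
        report = run_survival_analysis(recs)
        if report.cox is None:
            assert any("Cox stage" in n for n in report.notes)

    def test_subgroup_filter_to_empty_class_errors(self):
        records, _ = generate_cohort(SyntheticCohortConfig(seed=1))
        with pytest.raises((AnalysisError, StageError)):
            run_survival_analysis(
                records, AnalysisConfig(subgroup={"idh": "mutant"})
            )

    def test_threshold_override_used_in_km_stage(self):
        records, _ = generate_cohort(SyntheticCohortConfig(seed=1))
        report = run_survival_analysis(
            records,
            AnalysisConfig(threshold_overrides={"ttp_min": 25.0}),
        )
        assert report.thresholds["ttp_min"] == 25.0
        assert ("ttp_min>=25", "os") in report.km_results
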