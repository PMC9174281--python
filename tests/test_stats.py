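"""Outcome statistics: policy-driven group tests, proportion test, ROC.

Frozen reference values were computed with R 4.3 (t.test, var.test,
wilcox.test with exact=FALSE, prop.test, cor.test method="spearman") as an
independent implementation.
"""

import numpy as np
import pytest
from scipy import stats as sps

from embryosync.lineage import CountCurve, SynchronyProfile
from embryosync.stats import (
    SynchronyCutoffClassifier,
    cohort_report,
    compare_count_curves,
    compare_groups,
    roc_analysis,
    spearman_correlation,
    two_proportion_test,
)

# samples drawn in R with set.seed(42): rnorm(12,10,2) and rnorm(15,12,2)
R_X = np.array(
    [12.741917, 8.870604, 10.726257, 11.265725, 10.808537, 9.787751,
     13.023044, 9.810682, 14.036847, 9.874572, 12.609739, 14.573291]
)
R_Y = np.array(
    [9.222279, 11.442422, 11.733357, 13.271901, 11.431494, 6.687089,
     7.119066, 14.640227, 11.386723, 8.437383, 11.656165, 14.429349,
     15.790387, 11.139062, 11.485461]
)


class TestCompareGroups:
    def test_identical_samples_give_p_near_one(self):
        x = R_X.copy()
        res = compare_groups(x, x)
        assert res.p_value >= 0.99

    def test_unequal_variances_select_welch(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 50)
        y = rng.normal(0, 2, 50)  # 4-fold variance ratio
        assert compare_groups(x, y).test_name == "welch_t"

    def test_equal_variance_normals_select_student(self):
        res = compare_groups(R_X, R_Y)
        assert res.test_name == "student_t"
        # frozen R t.test(x, y, var.equal=TRUE) p-value
        assert res.p_value == pytest.approx(0.8374932098, abs=1e-6)

    def test_forced_wilcoxon_matches_r(self):
        res = compare_groups(R_X, R_Y, policy="wilcoxon")
        # frozen R wilcox.test(x, y, exact=FALSE, correct=TRUE) p-value
        assert res.p_value == pytest.approx(0.8643947798, abs=1e-6)

    def test_variance_ratio_p_matches_r_var_test(self):
        res = compare_groups(R_X, R_Y)
        assert res.variance_ratio_p == pytest.approx(0.2437784782, abs=1e-6)

    def test_nonnormal_group_routes_to_rank_sum(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0, 1.5, 60)  # heavy-tailed: fails normality
        y = rng.normal(2, 1, 60)
        assert compare_groups(x, y).test_name == "wilcoxon_rank_sum"

    def test_constant_identical_groups_degenerate(self):
        res = compare_groups([5.0] * 4, [5.0] * 4)
        assert res.degenerate and res.p_value == 1.0

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestTwoProportionTest:
    def test_prospective_cohort_worked_example(self):
        # 4/34 born among asynchronous vs 19/40 among synchronous embryos
        p = two_proportion_test(4, 34, 19, 40)
        assert p == pytest.approx(0.0022278680, abs=1e-6)  # frozen R prop.test

    def test_equal_proportions_give_p_one(self):
        assert two_proportion_test(5, 10, 5, 10) == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self):
        assert two_proportion_test(7, 27, 3, 38) == pytest.approx(
            two_proportion_test(3, 38, 7, 27)
        )

    def test_matches_direct_yates_formula(self):
        """Oracle: the 2x2 chi-square with continuity correction, by hand."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            n1, n2 = rng.integers(5, 40, 2)
            k1, k2 = rng.integers(1, n1), rng.integers(1, n2)
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
            row = table.sum(1)
            col = table.sum(0)
            expected = np.outer(row, col) / table.sum()
            chi2 = ((np.abs(table - expected) - 0.5).clip(0) ** 2 / expected).sum()
            p_oracle = sps.chi2.sf(chi2, 1)
            assert two_proportion_test(k1, n1, k2, n2) == pytest.approx(
                p_oracle, abs=1e-9
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(5, 0, 1, 10)
        with pytest.raises(ValueError):
            two_proportion_test(11, 10, 1, 10)


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_correlation(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_r_on_frozen_sample(self):
        rho, p = spearman_correlation(R_X, R_Y[:12])
        assert rho == pytest.approx(0.05594405594, abs=1e-9)  # frozen R cor.test
        assert p == pytest.approx(0.8689803393, abs=0.01)  # R uses AS 89

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError):
            spearman_correlation([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


class TestRocAnalysis:
    def test_perfect_separation_reaches_accuracy_one(self):
        scores = np.array([0.1, 0.2, 0.3, 0.6, 0.7, 0.8])
        labels = ["born"] * 3 + ["abort"] * 3
        roc = roc_analysis(scores, labels)
        assert roc.accuracy.max() == 1.0
        assert roc.at_cutoff(roc.selected_cutoff)["accuracy"] == 1.0

    def test_retrospective_confusion_counts(self):
        # 7 of 27 aborts and 0 of 38 borns at or above the 0.15 cutoff
        scores = np.array([0.20] * 7 + [0.10] * 20 + [0.10] * 38)
        labels = np.array(["abort"] * 27 + ["born"] * 38)
        roc = roc_analysis(scores, labels)
        at = roc.at_cutoff(0.15)
        assert at["sensitivity"] == pytest.approx(7 / 27)
        assert at["specificity"] == 1.0
        assert at["accuracy"] == pytest.approx(45 / 65)
        assert roc.selected_cutoff == pytest.approx(0.15)

    def test_metric_monotonicity_in_cutoff(self):
        rng = np.random.default_rng(11)
        scores = rng.random(40)
        labels = rng.choice(["born", "abort"], 40)
        roc = roc_analysis(scores, labels)
        assert np.all(np.diff(roc.sensitivity) <= 0)
        assert np.all(np.diff(roc.specificity) >= 0)

    def test_brute_force_confusion_oracle(self):
        """Sweep metrics equal exhaustive confusion-matrix counting."""
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(6, 21))
            scores = np.round(rng.random(n), 2)
            labels = np.zeros(n, dtype=int)
            labels[rng.permutation(n)[: n // 2]] = 1
            if labels.sum() in (0, n):
                continue
            roc = roc_analysis(scores, labels)
            for i, cut in enumerate(roc.cutoffs):
                tp = sum(1 for s, l in zip(scores, labels) if s >= cut and l == 1)
                fn = sum(1 for s, l in zip(scores, labels) if s < cut and l == 1)
                tn = sum(1 for s, l in zip(scores, labels) if s < cut and l == 0)
                fp = sum(1 for s, l in zip(scores, labels) if s >= cut and l == 0)
                assert roc.sensitivity[i] == pytest.approx(tp / (tp + fn))
                assert roc.specificity[i] == pytest.approx(tn / (tn + fp))
                assert roc.accuracy[i] == pytest.approx((tp + tn) / n)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], ["born", "born"])

    def test_null_auc_centred_on_half(self):
        """Random scores with balanced labels: mean AUC over the sweep ~ 0.5."""
        rng = np.random.default_rng(23)
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        aucs = [roc_analysis(rng.random(20), labels).auc for _ in range(10_000)]
        assert abs(np.mean(aucs) - 0.5) <= 0.02


class TestCompareCountCurves:
    def _curve(self, counts, dt=1.0):
        c = np.asarray(counts)
        return CountCurve(
            times=np.arange(len(c)) * dt, raw_counts=c, cleaned_counts=c
        )

    def test_identical_groups_nothing_flagged(self):
        curves = [self._curve([2, 4, 8, 16]) for _ in range(6)]
        out = compare_count_curves(curves, [self._curve([2, 4, 8, 16])] * 6, [1.0, 2.0])
        assert not any(r["significant"] for r in out)

    def test_late_divergence_flags_only_late_times(self):
        rng = np.random.default_rng(17)
        # identical until t=30, group b stalls afterwards
        def curve(stall):
            counts = [2] * 10 + [4] * 10 + [8] * 10 + ([8] * 20 if stall else [16] * 20)
            c = np.asarray(counts) + rng.integers(0, 2, 50)
            c = np.maximum.accumulate(c)
            return CountCurve(times=np.arange(50.0), raw_counts=c, cleaned_counts=c)

        a = [curve(False) for _ in range(8)]
        b = [curve(True) for _ in range(8)]
        out = compare_count_curves(a, b, [10.0, 20.0, 35.0, 45.0])
        flagged = {r["time"] for r in out if r["significant"]}
        assert flagged <= {35.0, 45.0}
        assert 45.0 in flagged

    def test_single_time_matches_forced_wilcoxon(self):
        rng = np.random.default_rng(19)
        a = [self._curve(np.maximum.accumulate(rng.integers(2, 9, 5))) for _ in range(6)]
        b = [self._curve(np.maximum.accumulate(rng.integers(2, 9, 5))) for _ in range(6)]
        out = compare_count_curves(a, b, [3.0])
        xa = [c.cleaned_counts[3] for c in a]
        xb = [c.cleaned_counts[3] for c in b]
        direct = compare_groups(xa, xb, policy="wilcoxon")
        assert out[0]["result"].p_value == pytest.approx(direct.p_value)


def _profiles(cvs, prefix="e"):
    return [
        SynchronyProfile(f"{prefix}{i}", 0.05, cv, cv, "high" if cv >= 0.15 else "low")
        for i, cv in enumerate(cvs)
    ]


class TestCohortReport:
    def test_retrospective_fractions(self):
        # 7 high-CV aborts, 20 low aborts, 38 low borns
        profiles = _profiles([0.2] * 7 + [0.1] * 20 + [0.1] * 38)
        outcomes = {p.embryo_id: ("abort" if i < 27 else "born")
                    for i, p in enumerate(profiles)}
        rep = cohort_report(profiles, outcomes)
        assert rep["high_fraction_of_aborts"] * 100 == pytest.approx(25.9, abs=0.05)
        assert rep["high_fraction_of_all"] * 100 == pytest.approx(10.8, abs=0.1)

    def test_prospective_born_rates_and_p(self):
        # 34 high-CV embryos (4 born) vs 40 low-CV (19 born)
        profiles = _profiles([0.2] * 34 + [0.1] * 40)
        outcomes = {}
        for i, p in enumerate(profiles):
            born = (i < 4) or (34 <= i < 34 + 19)
            outcomes[p.embryo_id] = "born" if born else "abort"
        rep = cohort_report(profiles, outcomes)
        assert rep["born_rate_high"] == pytest.approx(4 / 34)
        assert rep["born_rate_low"] == pytest.approx(19 / 40)
        assert rep["born_rate_p"] == pytest.approx(0.002, abs=5e-4)

    def test_all_low_cv_skips_proportion_test(self):
        profiles = _profiles([0.05] * 6)
        outcomes = {p.embryo_id: "born" for p in profiles}
        with pytest.warns(UserWarning):
            rep = cohort_report(profiles, outcomes)
        assert rep["high_fraction_of_all"] == 0.0
        assert np.isnan(rep["born_rate_p"])

    def test_id_mismatch_lists_orphans(self):
        profiles = _profiles([0.1, 0.2])
        with pytest.raises(ValueError, match="e1"):
            cohort_report(profiles, {"e0": "born", "weird": "abort"})


class TestSynchronyCutoffClassifier:
    def test_fit_predict_recovers_separating_cutoff(self):
        scores = np.array([0.05, 0.08, 0.10, 0.12, 0.20, 0.22, 0.25, 0.30])
        labels = np.array(["born"] * 4 + ["abort"] * 4)
        clf = SynchronyCutoffClassifier().fit(scores, labels)
        assert 0.12 < clf.cutoff_ <= 0.20
        assert list(clf.predict([0.05, 0.3])) == ["born", "abort"]
        assert clf.score(scores, labels) == 1.0

    def test_sklearn_contract(self):
        from sklearn.base import clone

        clf = SynchronyCutoffClassifier(criterion="youden")
        cloned = clone(clf)
        assert cloned.get_params()["criterion"] == "youden"
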