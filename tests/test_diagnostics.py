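import itertools

import numpy as np
import pytest
from scipy import stats

from angioimr.diagnostics import (
    AgreementStats,
    ConfusionMatrix,
    bland_altman,
    confusion_matrix,
    diagnostic_metrics,
    reconstruct_confusion_from_summary,
    reproducibility_report,
    roc_auc,
    round_half_up,
    spearman_correlation,
    two_proportion_z,
)

# the unique matrix at n=201 consistent with printed 92.7/95.6/95.0 summaries
STUDY_CM = ConfusionMatrix(tp=38, fp=7, fn=3, tn=153)


class TestRounding:
    def test_half_up_not_bankers(self):
        assert round_half_up(92.65) == 92.7
        assert round_half_up(92.75) == 92.8
        assert round_half_up(0.25) == 0.3


class TestConfusionMatrix:
    def test_perfect_agreement(self):
        cm = confusion_matrix([30, 20], [30, 20])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 1)

    def test_false_positive(self):
        cm = confusion_matrix([30], [20])
        assert cm.fp == 1 and cm.total == 1

    def test_boundary_inclusive_both_sides(self):
        cm = confusion_matrix([25.0], [25.0])
        assert cm.tp == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_matrix([1, 2], [1])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        test = rng.uniform(5, 50, 40)
        ref = rng.uniform(5, 50, 40)
        perm = rng.permutation(40)
        a = diagnostic_metrics(confusion_matrix(test, ref))
        b = diagnostic_metrics(confusion_matrix(test[perm], ref[perm]))
        assert a == b


class TestDiagnosticMetrics:
    def test_study_size_matrix_metrics(self):
        rep = diagnostic_metrics(STUDY_CM)
        assert rep.sensitivity.pct == 92.7
        assert rep.specificity.pct == 95.6
        assert rep.ppv.pct == 84.4
        assert rep.npv.pct == 98.1
        assert rep.accuracy.pct == 95.0

    def test_wald_ci_endpoints(self):
        rep = diagnostic_metrics(STUDY_CM)
        assert (rep.accuracy.ci_low, rep.accuracy.ci_high) == (92.0, 98.0)
        assert (rep.sensitivity.ci_low, rep.sensitivity.ci_high) == (84.7, 100.0)
        assert (rep.specificity.ci_low, rep.specificity.ci_high) == (92.5, 98.8)
        assert (rep.npv.ci_low, rep.npv.ci_high) == (95.9, 100.0)
        assert (rep.ppv.ci_low, rep.ppv.ci_high) == (73.9, 95.0)

    def test_point_estimate_within_ci(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 40, 4)
            if tp + fp + fn + tn == 0:
                continue
            rep = diagnostic_metrics(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            for m in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv, rep.accuracy):
                if m.defined:
                    assert m.ci_low <= m.pct <= m.ci_high
                    assert 0.0 <= m.ci_low and m.ci_high <= 100.0

    def test_undefined_metric_flagged_not_raised(self):
        rep = diagnostic_metrics(ConfusionMatrix(tp=0, fp=2, fn=0, tn=5))
        assert not rep.sensitivity.defined
        assert rep.specificity.defined


class TestReconstruction:
    def test_study_summaries_give_unique_matrix(self):
        sols = reconstruct_confusion_from_summary(201, 92.7, 95.6, 95.0)
        assert sols == [STUDY_CM]

    def test_tiny_perfect_case(self):
        sols = reconstruct_confusion_from_summary(2, 100.0, 100.0, 100.0)
        assert ConfusionMatrix(1, 0, 0, 1) in sols

    def test_inconsistent_summaries_error(self):
        with pytest.raises(ValueError):
            reconstruct_confusion_from_summary(1, 50.0, 50.0, 10.0)

    def test_round_trip_on_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            tp, fn = int(rng.integers(1, 30)), int(rng.integers(0, 30))
            tn, fp = int(rng.integers(1, 60)), int(rng.integers(0, 30))
            cm = ConfusionMatrix(tp, fp, fn, tn)
            rep = diagnostic_metrics(cm)
            sols = reconstruct_confusion_from_summary(
                cm.total, rep.sensitivity.pct, rep.specificity.pct, rep.accuracy.pct
            )
            assert cm in sols


class TestBlandAltman:
    def test_identical_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])
        s = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s == AgreementStats(0.0, 0.0, 0.0, 0.0, 3)

    def test_constant_offset(self):
        s = bland_altman([1.0, 2.0, 3.0], [2.5, 3.5, 4.5])
        assert s.mean_diff == pytest.approx(1.5)
        assert s.sd_diff == 0.0

    def test_study_summary_limits(self):
        # closed form: mean 0.88, SD 4.75 -> LoA 0.88 +/- 1.96*4.75
        upper = 0.88 + 1.96 * 4.75
        lower = 0.88 - 1.96 * 4.75
        assert round(upper, 2) == 10.19
        assert round(lower, 2) == -8.43  # prints as -8.44 in some tables (rounding)

    def test_orientation_reference_minus_test(self):
        # test underestimates reference by 2 -> positive mean difference
        s = bland_altman([10.0, 12.0, 14.0], [12.0, 14.0, 16.0])
        assert s.mean_diff == pytest.approx(2.0)

    def test_loa_bracket_covers_95pct_gaussian(self):
        rng = np.random.default_rng(12)
        ref = rng.normal(20, 5, 20_000)
        test = ref - rng.normal(1.0, 3.0, 20_000)
        s = bland_altman(test, ref)
        d = ref - test
        frac = np.mean((d >= s.loa_low) & (d <= s.loa_high))
        assert frac == pytest.approx(0.95, abs=0.01)


class TestSpearman:
    def test_monotone_series(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman_correlation(x, x).r == pytest.approx(1.0)
        assert spearman_correlation(x, x[::-1]).r == pytest.approx(-1.0)

    def test_constant_series_undefined(self):
        res = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert not res.defined

    def test_matches_bruteforce_rank_computation(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 50, 12)
        y = x + rng.normal(0, 10, 12)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert spearman_correlation(x, y).r == pytest.approx(brute, rel=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 1, 4000)
        labels = rng.random(4000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_matches_all_pairs_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(6, 50))
            scores = np.round(rng.uniform(0, 10, n), 1)  # force some ties
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            pos = scores[labels]
            neg = scores[~labels]
            wins = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p, q in itertools.product(pos, neg)
            )
            brute = wins / (len(pos) * len(neg))
            assert roc_auc(scores, labels).auc == pytest.approx(brute, rel=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_delong_ci_brackets_auc(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.normal(0, 1, 100), rng.normal(1.2, 1, 40)])
        labels = np.concatenate([np.zeros(100), np.ones(40)])
        res = roc_auc(scores, labels)
        assert res.ci_low <= res.auc <= res.ci_high
        assert 0 < res.se < 0.2

    def test_auc_matches_sklearn_reference(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(20)
        scores = rng.uniform(0, 40, 300)
        labels = (scores + rng.normal(0, 8, 300)) > 20
        if labels.any() and not labels.all():
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), rel=1e-12
            )


class TestReproducibility:
    def test_identical_series(self):
        rep = reproducibility_report([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.r == pytest.approx(1.0)
        assert rep.p_paired_t == 1.0
        assert rep.agreement.mean_diff == 0.0

    def test_fixed_offset_recovered(self):
        a = np.array([10.0, 15.0, 20.0, 25.0])
        rep = reproducibility_report(a, a + 2.0)
        # differences are first-series minus second-series
        assert rep.agreement.mean_diff == pytest.approx(-2.0)

    def test_observer_noise_sd_recovered(self):
        rng = np.random.default_rng(44)
        a = rng.uniform(10, 40, 5000)
        b = a + rng.normal(0, 2.5, 5000)
        rep = reproducibility_report(a, b)
        assert rep.agreement.sd_diff == pytest.approx(2.5, rel=0.05)
        assert rep.r > 0.9


class TestTwoProportionZ:
    def test_equal_proportions_p_one(self):
        z, p = two_proportion_z(50, 100, 50, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        z, p = two_proportion_z(37, 42, 145, 150)
        z_ref, p_ref = proportions_ztest([37, 145], [42, 150])
        assert z == pytest.approx(z_ref, rel=1e-9)
        assert p == pytest.approx(p_ref, rel=1e-9)
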