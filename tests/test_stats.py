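"""Rank correlations, Mann-Whitney, ICC, TOST, Bonferroni, ROC."""

import itertools

import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.weightstats import ttost_paired

import facenorms as fn


class TestSpearman:
    def test_perfect_monotone_relations(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert fn.spearman_rho(x, x**3).rho == pytest.approx(1.0)
        assert fn.spearman_rho(x, -x).rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(5)
        x = np.round(rng.normal(size=20), 0)  # heavy ties
        y = np.round(x + rng.normal(size=20), 0)
        res = fn.spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(fn.ValidationError):
            fn.spearman_rho([1, 2, 3], [1, 2])
        with pytest.raises(fn.ValidationError):
            fn.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestPartialSpearman:
    def test_constant_covariate_reduces_to_plain_spearman(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=(2, 30))
        plain = fn.spearman_rho(x, y)
        partial = fn.partial_spearman(x, y, np.full(30, 2.0))
        assert partial.rho == pytest.approx(plain.rho, abs=1e-12)

    def test_shared_driver_is_partialled_out(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=2000)
        x = z + rng.normal(size=2000)
        y = 2 * z + rng.normal(size=2000)
        assert abs(fn.partial_spearman(x, y, z).rho) < 0.05

    def test_matches_rank_residual_oracle(self):
        """Partial rho equals the Pearson correlation of the residuals of
        ranks regressed on ranks of z."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            x, y, z = rng.normal(size=(3, 40))
            rx, ry, rz = sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)
            def resid(v):
                X = np.column_stack([np.ones_like(rz), rz])
                return v - X @ np.linalg.lstsq(X, v, rcond=None)[0]
            oracle = np.corrcoef(resid(rx), resid(ry))[0, 1]
            assert fn.partial_spearman(x, y, z).rho == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(9)
        x, y, z = rng.normal(size=(3, 60))
        mine = fn.partial_spearman(x, y, z)
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z", method="spearman"
        )
        assert mine.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert mine.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_degenerate_covariate_raises(self):
        x = np.arange(10.0)
        with pytest.raises(fn.DegenerateDistributionError):
            fn.partial_spearman(x, np.random.default_rng(0).normal(size=10), x)


class TestMannWhitney:
    def test_complete_separation(self):
        res = fn.mann_whitney_u([1, 2, 3], [4, 5, 6, 7])
        assert res.u1 == 0 and res.u2 == 12

    def test_u1_plus_u2_identity(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x, y = rng.normal(size=12), rng.normal(size=9)
            res = fn.mann_whitney_u(x, y)
            assert res.u1 + res.u2 == len(x) * len(y)

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        x = np.round(rng.normal(size=5), 0)
        y = np.round(rng.normal(0.5, 1, size=5), 0)  # ties likely
        res = fn.mann_whitney_u(x, y)
        assert res.method == "exact"
        pooled = np.concatenate([x, y])
        n1, n = len(x), len(pooled)

        def u_of(idx):
            xs = pooled[list(idx)]
            ys = np.delete(pooled, list(idx))
            return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

        center = n1 * (n - n1) / 2.0
        dev_obs = abs(res.u1 - center)
        count = total = 0
        for idx in itertools.combinations(range(n), n1):
            total += 1
            if abs(u_of(idx) - center) >= dev_obs - 1e-9:
                count += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_tie_free_exact_matches_scipy(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=8), rng.normal(size=7)
        res = fn.mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(fn.ValidationError):
            fn.mann_whitney_u([], [1, 2])


class TestIcc:
    def test_identical_sessions_give_one(self):
        s = np.array([30.0, 28, 33, 25, 29, 31])
        assert fn.icc_test_retest(s, s).icc == pytest.approx(1.0)

    def test_independent_sessions_give_near_zero(self):
        rng = np.random.default_rng(13)
        s1, s2 = rng.normal(size=(2, 2000))
        assert abs(fn.icc_test_retest(s1, s2).icc) < 0.05

    def test_frozen_six_subject_table(self):
        # ANOVA mean squares worked once by hand for this table; ICC(2,1)
        s1 = np.array([30.0, 28, 33, 25, 29, 31])
        s2 = np.array([29.0, 27, 33, 26, 27, 32])
        assert fn.icc_test_retest(s1, s2).icc == pytest.approx(0.9152542372881357, abs=1e-10)

    def test_matches_pingouin_icc2(self):
        rng = np.random.default_rng(14)
        subj = rng.normal(28, 3, size=40)
        s1 = subj + rng.normal(0, 1.5, size=40)
        s2 = subj + rng.normal(0.4, 1.5, size=40)
        mine = fn.icc_test_retest(s1, s2).icc
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "session": np.tile([1, 2], 40),
                "score": np.column_stack([s1, s2]).ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="session", ratings="score")
        icc_a1 = float(ref["ICC"].iloc[1])  # row 1: single measures, absolute agreement
        assert mine == pytest.approx(icc_a1, abs=1e-10)

    def test_zero_between_subject_variance_raises(self):
        with pytest.raises(fn.DegenerateDistributionError):
            fn.icc_test_retest([5.0, 5, 5, 5, 5], [5.0, 5, 5, 5, 5])


class TestTost:
    def test_equal_short_forms_are_equivalent(self):
        rng = np.random.default_rng(15)
        x = rng.normal(14.6, 2.2, size=30)
        y = x + rng.normal(0, 0.3, size=30)
        assert fn.tost_paired(x, y).equivalent

    def test_mean_outside_bounds_is_not_equivalent(self):
        rng = np.random.default_rng(16)
        y = rng.normal(14.0, 2.0, size=30)
        x = y + 1.0 + rng.normal(0, 0.1, size=30)
        res = fn.tost_paired(x, y)
        assert not res.equivalent

    def test_degrees_of_freedom_at_normative_n(self):
        rng = np.random.default_rng(17)
        x = rng.normal(14.6, 2.2, size=229)
        y = x + rng.normal(0.2, 1.0, size=229)
        assert fn.tost_paired(x, y).df == 228

    def test_matches_statsmodels_ttost(self):
        rng = np.random.default_rng(18)
        x = rng.normal(14.6, 2.2, size=60)
        y = x + rng.normal(0.1, 0.9, size=60)
        res = fn.tost_paired(x, y)
        p, (t1, p1, _), (t2, p2, _) = ttost_paired(x, y, -0.5, 0.5)
        assert res.t_lower == pytest.approx(t1, abs=1e-10)
        assert res.t_upper == pytest.approx(t2, abs=1e-10)
        assert max(res.p_lower, res.p_upper) == pytest.approx(p, abs=1e-12)

    def test_zero_variance_conventions(self):
        x = np.full(10, 14.0)
        assert fn.tost_paired(x, x - 0.2).equivalent        # dbar strictly inside
        assert not fn.tost_paired(x, x - 1.0).equivalent    # dbar outside


class TestBonferroni:
    def test_published_sixteen_test_family(self):
        adjusted = fn.bonferroni_alpha(0.05, 16)
        assert adjusted == pytest.approx(0.003125)
        assert round(adjusted, 3) == 0.003

    def test_single_test_and_invalid_k(self):
        assert fn.bonferroni_alpha(0.05, 1) == 0.05
        with pytest.raises(fn.ValidationError):
            fn.bonferroni_alpha(0.05, 0)

    def test_familywise_error_controlled_under_global_null(self):
        rng = np.random.default_rng(19)
        alpha, k, reps = 0.05, 16, 400
        threshold = fn.bonferroni_alpha(alpha, k)
        fwe = 0
        for _ in range(reps):
            p = rng.random(k)
            fwe += (p < threshold).any()
        assert fwe / reps <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / reps)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.arange(10.0), np.arange(20.0, 30.0)]
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        res = fn.roc_analysis(scores, labels)
        assert res.auc == 1.0
        assert res.sensitivity == res.specificity == 1.0

    def test_uninformative_scores_give_half_auc(self):
        rng = np.random.default_rng(20)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.3
        assert fn.roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_u_statistic_identity(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n_pos, n_neg = rng.integers(3, 15, size=2)
            scores = np.round(rng.normal(size=n_pos + n_neg), 0)
            labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
            if len(np.unique(scores)) < 2:
                continue
            res = fn.roc_analysis(scores, labels)
            u = fn.mann_whitney_u(scores[~labels], scores[labels])
            assert res.auc == pytest.approx(u.u1 / (n_pos * n_neg), abs=1e-12)

    def test_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(22)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.25
        scores[labels] -= 1.0
        assert fn.roc_analysis(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, -scores), abs=1e-12
        )

    def test_cutoff_maximizes_youden(self):
        rng = np.random.default_rng(23)
        scores = rng.normal(size=120)
        labels = rng.random(120) < 0.4
        scores[labels] -= 1.2
        res = fn.roc_analysis(scores, labels)
        j_at_cut = res.sensitivity + res.specificity - 1.0
        pos, neg = scores[labels], scores[~labels]
        uniq = np.unique(scores)
        for c in (uniq[:-1] + uniq[1:]) / 2:
            j = (pos <= c).mean() + (neg > c).mean() - 1.0
            assert j <= j_at_cut + 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(fn.ValidationError):
            fn.roc_analysis([1.0, 2.0], [True, True])


class TestConfusionFromRates:
    @pytest.mark.parametrize(
        "sens, spec, n_pos, n_neg, tp, tn, acc",
        [
            (0.7857, 0.8077, 14, 26, 11, 21, 80.00),
            (0.7857, 0.7991, 14, 229, 11, 183, 79.84),
            (1.0, 1.0, 10, 10, 10, 10, 100.00),
        ],
    )
    def test_reported_clinical_accuracies(self, sens, spec, n_pos, n_neg, tp, tn, acc):
        res = fn.confusion_from_rates(sens, spec, n_pos, n_neg)
        assert res["tp"] == tp and res["tn"] == tn
        assert res["accuracy_percent"] == pytest.approx(acc, abs=1e-9)

    def test_invalid_rate_rejected(self):
        with pytest.raises(fn.ValidationError):
            fn.confusion_from_rates(1.2, 0.5, 10, 10)
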