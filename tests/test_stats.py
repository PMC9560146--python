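"""Cohort statistics: labelling, ROC/Youden, tests, agreement."""

import numpy as np
import pytest
from scipy import stats as sps

from dscfrac import (
    bland_altman,
    classify_outcome,
    cohen_kappa,
    fisher_exact,
    hosmer_lemeshow,
    icc_consistency,
    logistic_model,
    mann_whitney,
    median_iqr,
    method_agreement,
    roc_analysis,
    spearman_rho,
    threshold_sweep,
    youden_cutoff,
)


class TestClassifyOutcome:
    def test_25pct_increase_is_progression(self):
        lab = classify_outcome(10.0, 20.0, 20.0 * 1.30)
        assert lab.value == "TP"

    def test_regression_is_pseudoprogression(self):
        lab = classify_outcome(10.0, 20.0, 20.0 * 0.40)
        assert lab.value == "PsP"

    def test_stabilisation_is_pseudoprogression(self):
        lab = classify_outcome(10.0, 20.0, 20.0 * 1.10)
        assert lab.value == "PsP"
        assert lab.basis == "imaging_followup"

    def test_tp_flags_take_precedence(self):
        assert classify_outcome(10, 20, 8, new_lesion_outside_field=True).value == "TP"
        lab = classify_outcome(10, 20, 8, clinical_decline=True)
        assert lab.value == "TP" and lab.basis == "clinical_decline"

    def test_inclusion_requires_progression_at_crt1(self):
        with pytest.raises(ValueError, match="inclusion"):
            classify_outcome(20.0, 15.0, 10.0)


class TestMedianIqr:
    def test_moore_mccabe_odd_n(self):
        # n=7: median 4; halves exclude it
        vals = [1, 2, 3, 4, 5, 6, 7]
        assert median_iqr(vals) == (4.0, 2.0, 6.0)

    def test_even_n(self):
        vals = [1, 2, 3, 4]
        assert median_iqr(vals) == (2.5, 1.5, 3.5)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], float)
        labels = np.array(["PsP"] * 3 + ["TP"] * 3)
        roc = roc_analysis(scores, labels, n_boot=50)
        assert roc.auc == 1.0

    def test_all_tied_scores_give_half(self):
        scores = np.ones(10)
        labels = np.array(["PsP"] * 4 + ["TP"] * 6)
        assert roc_analysis(scores, labels, n_boot=50).auc == 0.5

    def test_auc_equals_concordance_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.normal(0, 1, n), 1)  # induce ties
            labels = np.where(rng.random(n) < 0.5, "PsP", "TP")
            if len(set(labels)) < 2:
                continue
            roc = roc_analysis(scores, labels, n_boot=10)
            pos = scores[labels == "PsP"]
            neg = scores[labels == "TP"]
            conc = np.mean(
                (pos[:, None] < neg[None, :])
                + 0.5 * (pos[:, None] == neg[None, :])
            )
            assert roc.auc == pytest.approx(conc, abs=1e-12)
            skl = roc_auc_score((labels == "PsP").astype(int), -scores)
            assert roc.auc == pytest.approx(skl, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(1, 9, 30)
        labels = np.where(rng.random(30) < 0.4, "PsP", "TP")
        base = roc_analysis(scores, labels, n_boot=10).auc
        for f in (np.log, np.sqrt, lambda s: 3 * s + 7, lambda s: s**3):
            assert roc_analysis(f(scores), labels, n_boot=10).auc == base

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_analysis([1.0, 2.0], ["PsP", "PsP"], n_boot=10)


class TestYouden:
    def test_fully_separated_j_is_one(self):
        scores = np.array([1, 2, 3, 10, 11, 12], float)
        labels = np.array(["PsP"] * 3 + ["TP"] * 3)
        cut = youden_cutoff(scores, labels)
        assert cut.youden_j == pytest.approx(1.0)
        assert cut.cutoff == pytest.approx(6.5)

    def test_matches_dense_grid_scan(self, rng):
        scores = rng.uniform(0, 100, 24)
        labels = np.where(rng.random(24) < 0.45, "PsP", "TP")
        cut = youden_cutoff(scores, labels)
        pos = labels == "PsP"

        def j_at(c):
            return (scores[pos] < c).mean() + (scores[~pos] >= c).mean() - 1

        # J is piecewise constant: a dense grid can only lower-bound it,
        # while the exact step set (all observed values and midpoints)
        # must reproduce the returned maximum
        grid = np.linspace(scores.min() - 1, scores.max() + 1, 1000)
        assert cut.youden_j >= max(j_at(c) for c in grid) - 1e-12
        v = np.sort(np.unique(scores))
        steps = np.r_[v[0] - 1, (v[:-1] + v[1:]) / 2, v, v[-1] + 1]
        assert cut.youden_j == pytest.approx(
            max(j_at(c) for c in steps), abs=1e-12
        )

    def test_sens_spec_match_confusion_matrix(self, rng):
        scores = rng.normal(50, 15, 30)
        labels = np.where(rng.random(30) < 0.5, "PsP", "TP")
        cut = youden_cutoff(scores, labels)
        pos = labels == "PsP"
        called = scores < cut.cutoff
        assert cut.sensitivity == (called & pos).sum() / pos.sum()
        assert cut.specificity == (~called & ~pos).sum() / (~pos).sum()


class TestThresholdSweep:
    def _records(self, rng, n=20):
        labels = np.array(["PsP"] * (n // 2) + ["TP"] * (n // 2))
        maps = []
        for lab in labels:
            base = rng.uniform(20, 40) if lab == "PsP" else rng.uniform(45, 70)
            maps.append(
                {x: max(0.0, base - 12 * (x - 2.0) + rng.normal(0, 2))
                 for x in (1.5, 1.75, 2.0, 2.25, 2.5, 2.75, 3.0)}
            )
        return maps, labels

    def test_seven_rows_and_best_flag(self, rng):
        maps, labels = self._records(rng)
        df = threshold_sweep(maps, labels, n_boot=20)
        assert len(df) == 7
        assert df["is_best"].sum() >= 1
        assert df.loc[df["is_best"], "auc"].iloc[0] == df["auc"].max()

    def test_identical_scores_identical_auc(self, rng):
        maps, labels = self._records(rng)
        for m in maps:
            m[3.0] = m[2.75]  # duplicate column
        df = threshold_sweep(maps, labels, n_boot=20).set_index("x")
        assert df.loc[3.0, "auc"] == df.loc[2.75, "auc"]

    def test_missing_threshold_key_rejected(self, rng):
        maps, labels = self._records(rng)
        del maps[3][2.5]
        with pytest.raises(KeyError):
            threshold_sweep(maps, labels, n_boot=20)


class TestLogistic:
    def test_null_covariate_slope_near_zero(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.integers(0, 2, 200).astype(float)
        fit = logistic_model(x, y)
        assert fit.converged
        assert abs(fit.slope) < 0.35

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.normal(0, 1, 60)
        y = (rng.random(60) < 1 / (1 + np.exp(-(0.5 + 1.2 * x)))).astype(float)
        fit = logistic_model(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)

    def test_loglik_beats_parameter_grid(self, rng):
        x = rng.normal(0, 1, 40)
        y = (rng.random(40) < 0.5).astype(float)
        fit = logistic_model(x, y)
        b0 = np.linspace(fit.intercept - 2, fit.intercept + 2, 200)
        b1 = np.linspace(fit.slope - 2, fit.slope + 2, 200)
        eta = b0[:, None, None] + b1[None, :, None] * x[None, None, :]
        p = np.clip(1 / (1 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        ll = (y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=-1)
        assert fit.log_likelihood >= ll.max() - 1e-9

    def test_complete_separation_flagged(self):
        x = np.array([1, 2, 3, 4, 10, 11, 12, 13], float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        fit = logistic_model(x, y)
        assert not fit.converged

    def test_zero_variance_covariate(self):
        with pytest.raises(ValueError, match="variance"):
            logistic_model(np.ones(10), np.r_[np.zeros(5), np.ones(5)])


class TestHosmerLemeshow:
    def test_chi2_nonnegative_and_df(self, rng):
        p = rng.uniform(0.05, 0.95, 200)
        y = (rng.random(200) < p).astype(float)
        chi2, df, pval = hosmer_lemeshow(p, y)
        assert chi2 >= 0
        assert df == 8
        assert 0 <= pval <= 1

    def test_identical_probabilities_collapse(self):
        p = np.full(50, 0.3)
        y = np.zeros(50)
        with pytest.raises(ValueError, match="bins"):
            hosmer_lemeshow(p, y)

    def test_calibrated_model_rejects_at_nominal_rate(self):
        # fitted logistic on data generated from a logistic truth: HL
        # p-values should be roughly uniform (5% rejections at alpha=.05)
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(0, 1, 150)
            p_true = 1 / (1 + np.exp(-(0.3 + 0.9 * x)))
            y = (rng.random(150) < p_true).astype(float)
            fit = logistic_model(x, y)
            _, _, pv = hosmer_lemeshow(fit.fitted, y)
            rejections += pv < 0.05
        assert 0.01 <= rejections / reps <= 0.10


class TestRankTests:
    def test_identical_groups_p_one(self):
        u, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_extreme_p(self):
        # all 20 arrangements of {1..6} into two triples: U=0 is one of
        # the two most extreme, so two-sided p = 2/20
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_u_identity(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 9)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == len(a) * len(b)

    def test_exact_and_asymptotic_agree_moderate_n(self, rng):
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(0.8, 1.0, 8)
        _, p_auto = mann_whitney(a, b)  # exact branch (tie-free, n=8)
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
        assert abs(p_auto - res.pvalue) < 0.01


class TestFisher:
    def test_balanced_table_p_one(self):
        # 2x2 gender-by-group split with no association
        assert fisher_exact([[5, 6], [6, 8]]) == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        # P(table | margins) = C(5,5)C(5,0)/C(10,5) = 1/252 per extreme
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_transpose_symmetry(self, rng):
        t = rng.integers(0, 12, (2, 2))
        t[t.sum(axis=1) == 0, 0] = 1
        assert fisher_exact(t) == pytest.approx(fisher_exact(t.T))

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x**3) == pytest.approx(1.0)
        assert spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        rho = spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


class TestAgreement:
    def test_bland_altman_identical(self):
        assert bland_altman([1, 2, 3], [1, 2, 3]) == (0.0, 0.0, 0.0)

    def test_bland_altman_constant_offset(self):
        a = np.array([3.0, 5.0, 9.0])
        bias, lo, hi = bland_altman(a - 0.48, a)
        assert bias == pytest.approx(-0.48)
        assert lo == pytest.approx(bias) and hi == pytest.approx(bias)

    def test_bias_inside_loa(self, rng):
        a, b = rng.normal(5, 2, 20), rng.normal(5, 2, 20)
        bias, lo, hi = bland_altman(a, b)
        assert lo <= bias <= hi

    def test_icc_perfect_and_shifted(self, rng):
        a = rng.normal(10, 3, 12)
        icc, _ = icc_consistency(np.column_stack([a, a]))
        assert icc == pytest.approx(1.0)
        icc, _ = icc_consistency(np.column_stack([a, a + 5.0]))
        assert icc == pytest.approx(1.0)  # consistency ignores fixed shift

    def test_icc_matches_anova_sums_oracle(self, rng):
        r = rng.normal(0, 1, (10, 2))
        icc, _ = icc_consistency(r)
        n, k = r.shape
        subj = r.mean(axis=1)
        rater = r.mean(axis=0)
        grand = r.mean()
        ssb = k * ((subj - grand) ** 2).sum()
        ssr = n * ((rater - grand) ** 2).sum()
        sse = ((r - grand) ** 2).sum() - ssb - ssr
        msb = ssb / (n - 1)
        mse = sse / ((n - 1) * (k - 1))
        oracle = (msb - mse) / (msb + (k - 1) * mse)
        assert icc == pytest.approx(oracle, abs=1e-10)

    def test_icc_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        r = rng.normal(5, 2, (12, 2)) + rng.normal(0, 1, (12, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "score": r.ravel(),
            }
        )
        ref = pg.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        icc, _ = icc_consistency(r)
        assert icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-9)

    def test_kappa_values(self):
        a = np.array(["P"] * 10 + ["N"] * 12 + ["P"] * 2 + ["N"])
        b = np.array(["P"] * 10 + ["N"] * 12 + ["N"] * 2 + ["P"])
        # confusion: [[10,2],[1,12]]
        po = 22 / 25
        pe = (12 / 25) * (11 / 25) + (13 / 25) * (14 / 25)
        assert cohen_kappa(a, b) == pytest.approx((po - pe) / (1 - pe))

    def test_kappa_perfect_and_constant(self):
        assert cohen_kappa(["A", "B", "A"], ["A", "B", "A"]) == 1.0
        assert cohen_kappa(["A", "A"], ["A", "A"]) == 1.0

    def test_method_agreement_bundle(self, rng):
        a = rng.normal(8, 3, 15)
        b = a + rng.normal(0, 0.5, 15)
        agg = method_agreement(a, b, labels1=a > 8, labels2=b > 8)
        assert agg.bland_altman[0] == pytest.approx(np.mean(a - b))
        assert -1 <= agg.kappa <= 1
        assert agg.icc[0] > 0.9
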