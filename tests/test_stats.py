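"""Statistical estimators: tests, LASSO, logistic, ROC, Pearson, ICC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import stentfai as sf
from stentfai.stats import StatsError, _mann_whitney_auc


class TestTwoSampleTest:
    def test_identical_samples(self):
        stat, p = sf.two_sample_test([1, 2, 3], [1, 2, 3])
        assert stat == 0.0 and p == 1.0

    def test_gross_separation(self):
        _, p = sf.two_sample_test([1, 2, 3], [11, 12, 13])
        assert p < 0.01

    def test_welch_vs_student_differ_under_heteroscedasticity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 5, 200)
        _, p_w = sf.two_sample_test(x, y, method="welch")
        _, p_s = sf.two_sample_test(x, y, method="student")
        assert p_w != p_s

    def test_small_sample_rejected(self):
        with pytest.raises(StatsError):
            sf.two_sample_test([1.0], [1.0, 2.0])


class TestCategoricalTest:
    def test_identical_proportions(self):
        _, p = sf.categorical_test([[30, 30], [30, 30]])
        assert p == pytest.approx(1.0)

    def test_hypertension_table_matches_hand_computed_chisquare(self):
        table = np.array([[31, 34], [28, 24]])
        stat, p = sf.categorical_test(table)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(chi2)
        assert p == pytest.approx(sps.chi2.sf(chi2, 1))
        assert p == pytest.approx(0.51, abs=0.02)

    def test_perfect_association(self):
        _, p = sf.categorical_test([[10, 0], [0, 10]])
        assert p < 0.001

    def test_small_expected_counts_use_fisher(self):
        table = [[2, 8], [9, 1]]
        stat, p = sf.categorical_test(table)
        assert p == pytest.approx(sps.fisher_exact(table).pvalue)

    def test_empty_margin_rejected(self):
        with pytest.raises(StatsError):
            sf.categorical_test([[0, 0], [5, 5]])


class TestLasso:
    def _strong_design(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 500, 21
        X = rng.normal(size=(n, p))
        y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * X[:, 0]))).astype(int)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(p)]), y

    def test_all_zero_at_lambda_max(self):
        from stentfai.stats import _l1_path_fit

        X, y = self._strong_design(0)
        Xs = (X - X.mean()) / X.std(ddof=0)
        n = len(y)
        lam_max = np.abs(Xs.to_numpy().T @ (y - y.mean())).max() / n
        coefs, _, _ = _l1_path_fit(Xs.to_numpy(), y, [lam_max * 1.001], n)
        assert np.abs(coefs).max() < 1e-8

    def test_strong_predictor_selected_at_lambda_1se(self):
        res = sf.lasso_select(*self._strong_design(1), seed=1)
        assert res.selected_1se == ["f0"]
        assert "f0" in res.selected_min
        assert res.lambda_1se >= res.lambda_min
        assert res.converged

    def test_path_endpoints(self):
        X, y = self._strong_design(2)
        res = sf.lasso_select(X, y, seed=2)
        # descending grid: heaviest penalty first (sparse), lightest last (dense)
        assert len(res.coef_1se) <= len(res.coef_min) + 5
        assert res.auc_min > 0.5

    def test_missing_values_rejected(self):
        X, y = self._strong_design(3)
        X.iloc[0, 0] = np.nan
        with pytest.raises(StatsError, match="missing"):
            sf.lasso_select(X, y)

    def test_fai_selected_on_calibrated_cohorts(self):
        """On cohorts drawn from the study's group parameters, the FAI is
        the dominant discriminator and survives the 1-SE penalty in the
        majority of seeds."""
        hits = 0
        seeds = range(5)
        for seed in seeds:
            df = sf.generate_cohort(sf.CohortConfig(seed=seed))
            cfg = sf.CohortConfig()
            feats = df[["peri_stent_fai_hu"] + list(cfg.continuous) + list(cfg.binary)]
            res = sf.lasso_select(feats, df.isr, seed=seed)
            hits += "peri_stent_fai_hu" in res.selected_1se
        assert hits > len(seeds) / 2


class TestAdjustedLogistic:
    def _cohort(self, seed, beta, n=1000):
        rng = np.random.default_rng(seed)
        fai = rng.normal(-82, 7, n)
        p = 1 / (1 + np.exp(-beta * (fai + 82)))
        df = pd.DataFrame(
            {
                "isr": (rng.random(n) < p).astype(int),
                "peri_stent_fai_hu": fai,
                "age_years": rng.normal(67, 10, n),
                "male": rng.integers(0, 2, n),
                "hyperlipidemia": rng.integers(0, 2, n),
                "diabetes": rng.integers(0, 2, n),
                "hypertension": rng.integers(0, 2, n),
                "smoking": rng.integers(0, 2, n),
                "prior_mi": rng.integers(0, 2, n),
            }
        )
        return df

    def test_null_predictor_ci_covers_one(self):
        covered = 0
        n_seeds = 30
        for seed in range(n_seeds):
            df = self._cohort(seed, 0.0)
            res = sf.fit_adjusted_logistic(df, ["peri_stent_fai_hu"])
            orr = res.odds_ratios["peri_stent_fai_hu"]
            covered += orr["ci_low"] <= 1.0 <= orr["ci_high"]
        assert covered >= 25  # ~95% coverage, binomial slack

    def test_known_slope_recovered(self):
        ors = []
        for seed in range(40):
            df = self._cohort(seed, np.log(2.0))
            res = sf.fit_adjusted_logistic(df, ["peri_stent_fai_hu"])
            ors.append(res.odds_ratios["peri_stent_fai_hu"]["or"])
        assert np.mean(ors) == pytest.approx(2.0, rel=0.05)

    def test_rank_deficient_design_rejected(self):
        df = self._cohort(0, 0.0)
        df["dup"] = df["peri_stent_fai_hu"]
        with pytest.raises(StatsError):
            sf.fit_adjusted_logistic(df, ["peri_stent_fai_hu", "dup"], adjusters=[])

    def test_separation_flagged(self):
        n = 60
        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(-5, 1, 30), rng.normal(5, 1, 30)]
        df = pd.DataFrame(
            {"isr": np.r_[np.zeros(30), np.ones(30)].astype(int), "x": x}
        )
        with pytest.warns(RuntimeWarning, match="separation"):
            res = sf.fit_adjusted_logistic(df, ["x"], adjusters=[])
        assert res.separation


class TestRoc:
    def test_perfect_separation(self):
        roc = sf.roc_curve_auc([1, 2, 9, 10], [0, 0, 1, 1])
        assert roc.auc == 1.0

    def test_uninformative_scores(self):
        roc = sf.roc_curve_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert roc.auc == 0.5

    def test_matches_exhaustive_pairwise_count(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            labels = np.zeros(n, int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = rng.integers(0, 5, n).astype(float)  # ties likely
            if labels.sum() in (0, n):
                continue
            roc = sf.roc_curve_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum(
                1.0 if a > b else 0.5 if a == b else 0.0
                for a in pos
                for b in neg
            )
            assert roc.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.4).astype(int)
        a = sf.roc_curve_auc(scores, labels).auc
        b = sf.roc_curve_auc(np.exp(scores) + 3, labels).auc
        assert a == pytest.approx(b)

    def test_delong_ci_contains_auc_and_shrinks(self):
        rng = np.random.default_rng(5)

        def one(n):
            pos = rng.normal(1, 1, n)
            neg = rng.normal(0, 1, n)
            roc = sf.roc_curve_auc(np.r_[pos, neg], np.r_[np.ones(n), np.zeros(n)])
            assert roc.ci[0] <= roc.auc <= roc.ci[1]
            return roc.ci[1] - roc.ci[0]

        assert one(500) < one(50)

    def test_single_class_rejected(self):
        with pytest.raises(StatsError):
            sf.roc_curve_auc([1, 2, 3], [1, 1, 1])


class TestYouden:
    def test_perfectly_separable(self):
        roc = sf.roc_curve_auc([1, 2, 9, 10], [0, 0, 1, 1])
        cutoff, sens, spec = sf.youden_cutoff(roc)
        assert sens + spec - 1 == pytest.approx(1.0)
        assert 2 < cutoff <= 9

    def test_antitone_relabeling_preserves_j(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=80)
        labels = (scores + rng.normal(0, 1, 80) > 0).astype(int)
        _, s1, p1 = sf.youden_cutoff(sf.roc_curve_auc(scores, labels))
        _, s2, p2 = sf.youden_cutoff(sf.roc_curve_auc(-scores, 1 - labels))
        assert (s1 + p1) == pytest.approx(s2 + p2)

    def test_binormal_specificity_closed_form(self):
        sens, spec = sf.binormal_operating_point(-82.5, -78.1, 6.2, -87.2, 7.3)
        assert spec == pytest.approx(sps.norm.cdf((-82.5 + 87.2) / 7.3))


class TestPearson:
    def test_collinear(self):
        x = np.arange(10.0)
        r, ci, p = sf.pearson_with_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_parameter_recovery_at_study_size(self):
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(500):
            z = rng.multivariate_normal([0, 0], [[1, 0.579], [0.579, 1]], size=52)
            rs.append(sf.pearson_with_ci(z[:, 0], z[:, 1])[0])
        assert np.mean(rs) == pytest.approx(0.579, abs=0.03)

    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(8)
        r, _, _ = sf.pearson_with_ci(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.08

    def test_fisher_ci_coverage(self):
        rng = np.random.default_rng(9)
        rho = 0.5
        cov = [[1, rho], [rho, 1]]
        hits = 0
        reps = 500
        for _ in range(reps):
            z = rng.multivariate_normal([0, 0], cov, size=50)
            _, ci, _ = sf.pearson_with_ci(z[:, 0], z[:, 1])
            hits += ci[0] <= rho <= ci[1]
        assert hits / reps == pytest.approx(0.95, abs=0.03)

    def test_constant_input_rejected(self):
        with pytest.raises(StatsError):
            sf.pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])


class TestIcc:
    def test_identical_raters(self):
        x = np.arange(10.0)
        res = sf.icc_absolute(np.c_[x, x])
        assert res.estimate == pytest.approx(1.0)

    def test_matches_pingouin_absolute_agreement(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        subj = rng.normal(-82, 7, 40)
        ratings = np.c_[
            subj + rng.normal(0, 0.85, 40), subj + rng.normal(0, 0.85, 40)
        ]
        ours = sf.icc_absolute(ratings)
        long = pd.DataFrame(
            {
                "s": np.repeat(np.arange(40), 2),
                "r": np.tile([0, 1], 40),
                "v": ratings.ravel(),
            }
        )
        tab = pg.intraclass_corr(long, targets="s", raters="r", ratings="v")
        ref = float(tab.loc[tab.Type == "ICC(A,1)", "ICC"].iloc[0])
        assert ours.estimate == pytest.approx(ref, abs=1e-9)

    def test_variance_ratio_closed_form(self):
        """Subject SD 7 HU and rater noise SD 0.85 HU give an expected
        ICC of 49/(49+0.7225) ~ 0.985; the estimator must land there on
        average."""
        rng = np.random.default_rng(11)
        est = []
        for _ in range(200):
            subj = rng.normal(0, 7, 117)
            ratings = np.c_[
                subj + rng.normal(0, 0.85, 117), subj + rng.normal(0, 0.85, 117)
            ]
            est.append(sf.icc_absolute(ratings).estimate)
        assert np.mean(est) == pytest.approx(49 / (49 + 0.85**2), abs=0.01)

    def test_pure_noise_is_near_zero(self):
        rng = np.random.default_rng(12)
        est = [
            sf.icc_absolute(rng.normal(size=(50, 2))).estimate for _ in range(50)
        ]
        assert abs(np.mean(est)) < 0.1

    def test_constant_ratings_degenerate(self):
        res = sf.icc_absolute(np.full((10, 2), 3.0))
        assert res.degenerate


class TestSubgroupRoc:
    def test_single_stratum_equals_global(self):
        df = sf.generate_cohort(sf.CohortConfig(seed=13))
        df["all"] = "all"
        sub = sf.subgroup_roc(df, key="all")
        glob = sf.roc_curve_auc(df.peri_stent_fai_hu, df.isr)
        assert sub["all"].auc == pytest.approx(glob.auc)

    def test_one_class_stratum_is_undefined(self):
        df = sf.generate_cohort(sf.CohortConfig(seed=14))
        df.loc[df.vessel == "RCA", "isr"] = 0
        sub = sf.subgroup_roc(df)
        assert sub["RCA"] is None
        assert sub["LAD"] is not None
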