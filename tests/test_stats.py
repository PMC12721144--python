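"""Statistical stages: LMM, Friedman/Durbin-Conover, ART, FDR, PCA, power."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nnskit.lmm import RandomInterceptLMM
from nnskit.simulate import SimParams, null_params, simulate_cohort
from nnskit.stats import (
    PCA_FEATURES,
    PowerModelParams,
    art_anova,
    benjamini_hochberg,
    cohens_d,
    correlate_prenatal,
    durbin_conover,
    fit_condition_lmm,
    friedman_test,
    normality_screen,
    pca_baseline,
    power_sensitivity,
    subject_condition_matrix,
    summarize_by_condition,
)
from nnskit.types import FeatureTable, NNS_FEATURES

from conftest import brute_force_bh


def _table_from_values(values):
    """values: dict subject -> dict condition -> list of trial values (cycles_trial)."""
    rows = []
    for sid, conds in values.items():
        idx = 1
        for cond, vals in conds.items():
            for v in vals:
                row = {"subject_id": sid, "trial_index": idx, "condition": cond}
                row.update({f: v for f in NNS_FEATURES})
                rows.append(row)
                idx += 1
    return FeatureTable(pd.DataFrame(rows))


@pytest.fixture(scope="module")
def effect_cohort():
    """Rendered-free cohort with planted condition effects (30 subjects)."""
    return simulate_cohort(SimParams(n_subjects=30), seed=101, render=False)


class TestSummaries:
    def test_identical_subjects_give_zero_sd(self):
        table = _table_from_values(
            {"A": {"baseline": [5.0, 5.0]}, "B": {"baseline": [5.0]}}
        )
        s = summarize_by_condition(table)
        row = s[(s.condition == "baseline") & (s.feature == "cycles_trial")].iloc[0]
        assert row["mean"] == 5.0 and row["sd"] == 0.0

    def test_single_subject_sd_missing(self):
        table = _table_from_values({"A": {"baseline": [5.0, 7.0]}})
        s = summarize_by_condition(table)
        row = s[(s.condition == "baseline") & (s.feature == "cycles_trial")].iloc[0]
        assert np.isnan(row["sd"]) and row["n"] == 1

    def test_planted_shift_recovered(self, effect_cohort):
        params = effect_cohort.params
        s = summarize_by_condition(effect_cohort.true_features)
        s = s[s.feature == "cycles_trial"].set_index("condition")["mean"]
        planted = params.expected_cycles_per_trial("baseline") - params.expected_cycles_per_trial("synthesized")
        assert s["baseline"] - s["synthesized"] == pytest.approx(planted, abs=3.5)

    def test_cohens_d_shift_invariance(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(0, 1, 20), rng.normal(1, 1, 20)
        assert cohens_d(x1 + 100.0, x2 + 100.0) == pytest.approx(cohens_d(x1, x2), abs=1e-12)


class TestConditionLMM:
    def test_matches_statsmodels_mixedlm(self, effect_cohort):
        """Independent cross-check of the REML engine on real pipeline data."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        df = effect_cohort.true_features.df
        res = fit_condition_lmm(effect_cohort.true_features, "cycles_trial")
        X = np.column_stack(
            [np.ones(len(df))]
            + [(df.condition == c).to_numpy(float) for c in ("narrated", "hummed", "synthesized")]
        )
        sm_fit = MixedLM(df.cycles_trial.to_numpy(), X, groups=df.subject_id).fit(reml=True)
        np.testing.assert_allclose(res.fit.beta, sm_fit.fe_params, rtol=1e-4)
        assert res.fit.sigma2_e == pytest.approx(sm_fit.scale, rel=1e-3)
        assert res.fit.sigma2_b == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-3)

    def test_zero_variance_reproduces_ols_f(self):
        rng = np.random.default_rng(1)
        n_sub, reps = 8, 4
        subj = np.repeat(np.arange(n_sub), reps)
        cond = np.tile(np.arange(reps), n_sub)
        X = np.column_stack([np.ones(len(subj))] + [(cond == k).astype(float) for k in (1, 2, 3)])
        y = rng.normal(0, 1, len(subj))
        fit = RandomInterceptLMM(y, X, subj).fit(force_zero_variance=True)
        L = np.zeros((3, 4)); L[0, 1] = L[1, 2] = L[2, 3] = 1.0
        import statsmodels.api as sm

        ols = sm.OLS(y, X).fit()
        assert fit.wald_f(L).f == pytest.approx(float(ols.f_test(L).fvalue), abs=1e-6)

    def test_planted_synthesized_effect_estimated(self, effect_cohort):
        params = effect_cohort.params
        res = fit_condition_lmm(effect_cohort.true_features, "cycles_trial")
        est = next(c for c in res.contrasts if c.pair == ("baseline", "synthesized"))
        planted = params.expected_cycles_per_trial("baseline") - params.expected_cycles_per_trial("synthesized")
        assert est.estimate == pytest.approx(planted, abs=4.0)
        assert est.p_adj < 0.001
        assert np.sign(est.d) == np.sign(est.estimate)

    def test_constant_condition_rejected(self):
        table = _table_from_values(
            {"A": {"baseline": [1.0, 2.0]}, "B": {"baseline": [2.0, 3.0]}}
        )
        with pytest.raises(ValueError, match="no contrast estimable"):
            fit_condition_lmm(table, "cycles_trial")

    def test_singular_fit_reported_not_raised(self):
        rng = np.random.default_rng(2)
        rows = {}
        for i in range(6):
            rows[f"S{i}"] = {c: list(rng.normal(10, 1, 3))
                             for c in ("baseline", "narrated", "hummed", "synthesized")}
        table = _table_from_values(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_condition_lmm(table, "cycles_trial")
        assert res.fit.singular
        assert res.warnings
        assert np.all(np.isfinite(res.fit.beta))


class TestFriedman:
    def test_hand_formula_perfect_ordering(self):
        M = np.array([[1, 2, 3], [1, 2, 3], [1, 2, 3]], dtype=float)
        chi2, df, p = friedman_test(M)
        assert chi2 == pytest.approx(6.0)
        assert df == 2

    def test_no_rank_variation_gives_zero(self):
        M = np.array([[2.0, 2.0, 2.0]] * 4)
        chi2, _, p = friedman_test(M)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(8, 4))
        chi2, _, _ = friedman_test(M)
        chi2p, _, _ = friedman_test(M[:, [2, 0, 3, 1]])
        assert chi2p == pytest.approx(chi2)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(6)
        M = rng.normal(size=(10, 4))
        chi2, _, p = friedman_test(M)
        ref = sps.friedmanchisquare(*[M[:, j] for j in range(4)])
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_exhaustive_small_matrices_match_manual_ranks(self):
        """All 3x3 matrices over {1,2,3}: formula agrees with count-based ranking."""
        from itertools import product

        def manual_chi2(M):
            n, k = M.shape
            R = np.zeros(k)
            for row in M:
                for j in range(k):
                    less = np.sum(row < row[j])
                    equal = np.sum(row == row[j])
                    R[j] += less + (equal + 1) / 2.0
            return 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3 * n * (k + 1)

        rng = np.random.default_rng(0)
        cells = list(product([1, 2, 3], repeat=9))
        for flat in rng.choice(len(cells), size=400, replace=False):
            M = np.array(cells[flat], dtype=float).reshape(3, 3)
            chi2, _, _ = friedman_test(M)
            assert chi2 == pytest.approx(manual_chi2(M), abs=1e-10)

    def test_missing_cells_instruct_aggregation(self):
        M = np.array([[1.0, np.nan, 3.0], [1, 2, 3]])
        with pytest.raises(ValueError, match="aggregate"):
            friedman_test(M)


class TestDurbinConover:
    def test_equal_rank_sums_give_zero_t(self):
        M = np.array([[1, 2, 3], [2, 3, 1], [3, 1, 2]], dtype=float)  # latin square
        res = durbin_conover(pd.DataFrame(M, columns=list("abc")))
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_perfect_ordering_symmetry(self):
        M = np.array([[1, 2, 3]] * 3, dtype=float)
        res = durbin_conover(pd.DataFrame(M, columns=list("abc")))
        t_ab = res[res.pair == ("a", "b")]["t"].iloc[0]
        t_bc = res[res.pair == ("b", "c")]["t"].iloc[0]
        assert abs(t_ab) == pytest.approx(abs(t_bc))
        assert res["df"].iloc[0] == 4  # (n-1)(k-1)

    def test_p_monotone_in_rank_sum_gap(self):
        rng = np.random.default_rng(8)
        M = rng.normal(size=(12, 4)) + np.array([0.0, 0.5, 1.0, 2.0])
        res = durbin_conover(pd.DataFrame(M, columns=list("abcd")))
        ranks = np.apply_along_axis(sps.rankdata, 1, M)
        sums = dict(zip("abcd", ranks.sum(axis=0)))
        gaps = res["pair"].map(lambda pr: abs(sums[pr[0]] - sums[pr[1]]))
        order = np.argsort(gaps.to_numpy())
        ps = res["p"].to_numpy()[order]
        assert np.all(np.diff(ps) <= 1e-12)

    def test_two_conditions_rejected(self):
        with pytest.raises(ValueError, match="k >= 3"):
            durbin_conover(np.ones((4, 2)))


class TestART:
    def test_positive_rescaling_invariance(self, effect_cohort):
        """Alignment is equivariant under y -> a y (a > 0), so ranks and F match.

        A power-of-two scale keeps the floating-point alignment exact;
        general affine maps preserve ranks in exact arithmetic but can
        flip ties at the last ulp.
        """
        table = effect_cohort.true_features
        f1 = art_anova(table, "cycles_trial")
        df2 = table.df.copy()
        df2["cycles_trial"] = 4.0 * df2["cycles_trial"]
        f2 = art_anova(FeatureTable(df2), "cycles_trial")
        assert f2.f == pytest.approx(f1.f, rel=1e-9)

    def test_planted_large_effect_detected(self, effect_cohort):
        res = art_anova(effect_cohort.true_features, "cycles_trial")
        assert res.p < 0.001


class TestFDR:
    def test_worked_vector(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.uniform(0, 1, m)
            np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p), atol=1e-15)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 50)
        assert np.all(benjamini_hochberg(p) >= p - 1e-15)


class TestCorrelations:
    def test_covariate_identical_to_feature(self, effect_cohort):
        table = effect_cohort.true_features
        subj = table.subject_level()
        base = subj[subj.condition == "baseline"]
        q = pd.DataFrame({"subject_id": base.subject_id,
                          "womb_talk_week": base.cycles_trial})
        res = correlate_prenatal(table, q, "baseline",
                                 feature_names=["cycles_trial"],
                                 covariates=["womb_talk_week"])
        row = res.table.iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p_adj < 1e-10

    def test_planted_link_sign_recovered(self):
        params = null_params(SimParams(n_subjects=100))
        cohort = simulate_cohort(params, seed=31, render=False)
        from nnskit.io import questionnaire_frame

        res = correlate_prenatal(cohort.true_features, questionnaire_frame(cohort.questionnaires),
                                 "baseline")
        row = res.table[(res.table.feature == "cycles_trial")
                        & (res.table.covariate == "womb_talk_week")].iloc[0]
        assert row.r > 0

    def test_insufficient_pairs_flagged(self, effect_cohort):
        table = effect_cohort.true_features
        subj_ids = table.subjects()[:2]
        q = pd.DataFrame({"subject_id": subj_ids, "talk_day": [1, 2]})
        res = correlate_prenatal(table, q, "baseline", covariates=["talk_day"])
        assert (res.table.flag == "insufficient data").all()
        assert res.table.r.isna().all()


class TestPCA:
    def test_proportions_sum_to_one(self, effect_cohort):
        res = pca_baseline(effect_cohort.true_features)
        assert res.proportion.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.n_components == 2

    def test_loadings_orthonormal(self, effect_cohort):
        res = pca_baseline(effect_cohort.true_features, n_components=len(PCA_FEATURES))
        V = res.loadings.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)

    def test_square_cosines_bounded(self, effect_cohort):
        res = pca_baseline(effect_cohort.true_features, n_components=len(PCA_FEATURES))
        sums = res.square_cosines.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-8)
        res2 = pca_baseline(effect_cohort.true_features, n_components=2)
        assert (res2.square_cosines.sum(axis=1) <= 1.0 + 1e-9).all()

    def test_joint_scaling_invariance(self, effect_cohort):
        table = effect_cohort.true_features
        res1 = pca_baseline(table)
        df = table.df.copy()
        for f in NNS_FEATURES:
            df[f] = df[f] * 10.0
        res2 = pca_baseline(FeatureTable(df))
        np.testing.assert_allclose(res2.proportion, res1.proportion, atol=1e-10)

    def test_full_reconstruction(self, effect_cohort):
        res = pca_baseline(effect_cohort.true_features, n_components=len(PCA_FEATURES))
        X = res.transformed.to_numpy()
        recon = res.scores @ res.loadings.to_numpy().T + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-10)

    def test_two_factor_structure_recovered(self):
        """Features built from 2 latent factors: first two components dominate."""
        rng = np.random.default_rng(21)
        n = 60
        f = rng.normal(size=(n, 2))
        load = rng.normal(size=(2, len(PCA_FEATURES)))
        latent = f @ load
        noise = rng.normal(scale=np.sqrt(latent.var(axis=0) / 9.0), size=latent.shape)
        X = np.exp(0.3 * (latent + noise))  # positive scale, undone by the log transform
        rows = []
        for i in range(n):
            row = {"subject_id": f"S{i}", "trial_index": 1, "condition": "baseline"}
            row.update({feat: X[i, j] for j, feat in enumerate(PCA_FEATURES)})
            row["bursts_trial"] = 1.0
            rows.append(row)
        res = pca_baseline(FeatureTable(pd.DataFrame(rows)))
        assert res.cumulative[1] >= 0.85


@pytest.fixture(scope="module")
def power_curve():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return power_sensitivity(
            PowerModelParams(), effect_grid=[0.0, 2.0, 6.5, 90.0],
            n_sims=80, rng=np.random.default_rng(33),
        )


class TestPowerSensitivity:

    def test_size_near_alpha_and_limits(self, power_curve):
        assert power_curve.power[0] <= 0.15  # effect 0: size ~ alpha
        assert power_curve.power[-1] == pytest.approx(1.0)  # 10 x residual SD

    def test_monotone_in_effect(self, power_curve):
        assert np.all(np.diff(power_curve.power) >= -0.05)

    def test_smallest_detectable_reported(self, power_curve):
        assert power_curve.smallest_detectable in (2.0, 6.5)


class TestNormalityScreen:
    def test_flags_route_to_nonparametrics(self):
        rng = np.random.default_rng(40)
        rows = []
        for i in range(50):
            normal_v = rng.normal(10, 1)
            skewed_v = float(np.exp(rng.normal(0, 1.2)))
            row = {"subject_id": f"S{i}", "trial_index": 1, "condition": "baseline"}
            row.update({f: normal_v for f in NNS_FEATURES})
            row["burst_duration"] = skewed_v
            rows.append(row)
        rows2 = []
        for i in range(50):  # second condition so the table has >= 2 conditions
            row = dict(rows[i])
            row["trial_index"] = 2
            row["condition"] = "narrated"
            rows2.append(row)
        screen = normality_screen(FeatureTable(pd.DataFrame(rows + rows2)))
        base = screen[screen.condition == "baseline"].set_index("feature")
        assert bool(base.loc["burst_duration", "non_normal"])
        assert not bool(base.loc["cycles_trial", "non_normal"])

    def test_small_cells_missing(self):
        table = _table_from_values({"A": {"baseline": [1.0]}, "B": {"baseline": [2.0]}})
        screen = normality_screen(table)
        assert screen[screen.condition == "baseline"]["W"].isna().all()


class TestNullCalibration:
    def test_lmm_type_i_error_near_alpha(self):
        """Reduced null study (120 cohorts) for the routine suite; the
        acceptance test runs the full 500."""
        params = null_params(SimParams(n_subjects=12))
        rej = 0
        N = 120
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(N):
                cohort = simulate_cohort(params, seed=20000 + s, render=False)
                if fit_condition_lmm(cohort.true_features, "cycles_trial").p < 0.05:
                    rej += 1
        se = np.sqrt(0.05 * 0.95 / N)
        assert abs(rej / N - 0.05) <= 3 * se
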