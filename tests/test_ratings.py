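import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spiralpref import ratings
from spiralpref.synthetic import DEFAULT_COEFFICIENTS, SynthConfig, gen_ratings


def matrix_from(arr, prefix="r"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestIcc:
    def test_identical_raters_give_one(self):
        m = matrix_from(np.tile([10.0, 20, 30, 40], (5, 1)))
        assert ratings.icc_consistency_avg(m) == pytest.approx(1.0)

    def test_additive_rater_shifts_give_one(self):
        base = np.array([10.0, 20, 30, 40, 55])
        m = matrix_from([base + shift for shift in (0, 5, -3, 12)])
        assert ratings.icc_consistency_avg(m) == pytest.approx(1.0, abs=1e-12)

    def test_three_by_three_manual_anova_oracle(self):
        # hand-computed two-way decomposition of a small table
        x = np.array([[1.0, 2, 4], [2, 4, 5], [4, 3, 9]])
        k, n = x.shape
        grand = x.mean()
        ms_stim = k * ((x.mean(0) - grand) ** 2).sum() / (n - 1)
        ss_resid = (
            ((x - grand) ** 2).sum()
            - k * ((x.mean(0) - grand) ** 2).sum()
            - n * ((x.mean(1) - grand) ** 2).sum()
        )
        ms_resid = ss_resid / ((n - 1) * (k - 1))
        expected = (ms_stim - ms_resid) / ms_stim
        got = ratings.icc_consistency_avg(matrix_from(x))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc3k(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        m = matrix_from(rng.uniform(1, 100, size=(8, 6)))
        long = m.stack().rename("rating").reset_index()
        long.columns = ["rater", "stimulus", "rating"]
        table = pingouin.intraclass_corr(
            long, targets="stimulus", raters="rater", ratings="rating"
        ).set_index("Type")
        assert ratings.icc_consistency_avg(m) == pytest.approx(
            table.loc["ICC(C,k)", "ICC"], abs=1e-8
        )

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            ratings.icc_consistency_avg(matrix_from(np.full((4, 4), 7.0)))


class TestClustering:
    def test_k1_explains_nothing(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.uniform(1, 100, (10, 5)))
        g = ratings.cluster_raters(m, k=1, restarts=5, seed=0)
        assert g.explained_variance == pytest.approx(0.0, abs=1e-12)

    def test_k_equals_distinct_rows_explains_everything(self):
        m = matrix_from([[1.0, 2, 3], [10, 20, 30], [5, 5, 5], [9, 1, 9]])
        g = ratings.cluster_raters(m, k=4, restarts=5, seed=0)
        assert g.explained_variance == pytest.approx(1.0, abs=1e-12)

    def test_recovers_synthetic_groups_low_noise(self, features_tbl):
        cfg = SynthConfig(residual_sd=5.0, intercept_sd=2.0, master_seed=11)
        matrix, labels, clip_rate = gen_ratings(cfg, features_tbl)
        assert clip_rate < 0.01
        g = ratings.cluster_raters(
            matrix, k=3, restarts=20, seed=0, dcm=features_tbl["dcm"]
        )
        assert adjusted_rand_score(labels, g.labels.reindex(labels.index)) >= 0.9

    def test_canonical_labels_follow_balance_preference(self, features_tbl):
        cfg = SynthConfig(residual_sd=5.0, intercept_sd=2.0, master_seed=3)
        matrix, labels, _ = gen_ratings(cfg, features_tbl)
        g = ratings.cluster_raters(
            matrix, k=3, restarts=20, seed=0, dcm=features_tbl["dcm"]
        )
        # generating labels and recovered canonical labels should agree by name
        agreement = (g.labels.reindex(labels.index) == labels).mean()
        assert agreement > 0.9

    def test_explained_variance_nondecreasing_in_k(self, features_tbl):
        cfg = SynthConfig(master_seed=5)
        matrix, _, _ = gen_ratings(cfg, features_tbl)
        ev = [
            ratings.cluster_raters(matrix, k=k, restarts=20, seed=0).explained_variance
            for k in (1, 2, 3, 4)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(ev, ev[1:]))

    def test_k_exceeding_raters_rejected(self):
        m = matrix_from(np.eye(3) * 10)
        with pytest.raises(ValueError):
            ratings.cluster_raters(m, k=5, restarts=2, seed=0)


class TestProfilesAndCorrelations:
    def test_single_group_profile_is_column_mean(self):
        m = matrix_from([[1.0, 2, 3], [3, 4, 5]])
        g = ratings.cluster_raters(m, k=1, restarts=2, seed=0)
        prof = ratings.group_profiles(m, g)
        assert np.allclose(prof.iloc[0], m.mean(axis=0))

    def test_group_size_weighted_profiles_reproduce_grand_mean(self, features_tbl):
        cfg = SynthConfig(master_seed=2)
        matrix, labels, _ = gen_ratings(cfg, features_tbl)
        g = ratings.cluster_raters(matrix, k=3, restarts=10, seed=0, dcm=features_tbl["dcm"])
        prof = ratings.group_profiles(matrix, g)
        sizes = pd.Series(g.sizes).reindex(prof.index)
        weighted = (prof.mul(sizes, axis=0)).sum() / sizes.sum()
        assert np.allclose(weighted, matrix.mean(axis=0))

    def test_recovered_profiles_close_to_generating(self, features_tbl):
        cfg = SynthConfig(residual_sd=5.0, intercept_sd=2.0, master_seed=13)
        matrix, labels, _ = gen_ratings(cfg, features_tbl)
        g = ratings.GroupAssignment(
            labels=labels, centroids=pd.DataFrame(), explained_variance=0.0
        )
        prof = ratings.group_profiles(matrix, g)
        X = features_tbl[["width", "path_length", "dcm"]].to_numpy()
        for grp in ("A", "L", "G"):
            beta = DEFAULT_COEFFICIENTS[grp]
            truth = beta["Intercept"] + X @ np.array(
                [beta["width"], beta["path_length"], beta["dcm"]]
            )
            n = (labels == grp).sum()
            sem = np.sqrt(5.0**2 + 2.0**2) / np.sqrt(n)
            assert np.all(np.abs(prof.loc[grp].to_numpy() - truth) < 4 * sem)

    def test_profile_proportional_to_feature_gives_r_one(self, features_tbl):
        prof = pd.DataFrame(
            [2.0 * features_tbl["dcm"] + 5.0], index=["A"],
        )
        r, _ = ratings.rating_feature_correlations(prof, features_tbl)
        assert r.loc["A", "dcm"] == pytest.approx(1.0)

    def test_synthetic_group_a_sign_pattern(self, features_tbl):
        cfg = SynthConfig(residual_sd=5.0, intercept_sd=2.0, master_seed=17)
        matrix, labels, _ = gen_ratings(cfg, features_tbl)
        g = ratings.GroupAssignment(
            labels=labels, centroids=pd.DataFrame(), explained_variance=0.0
        )
        prof = ratings.group_profiles(matrix, g)
        r, _ = ratings.rating_feature_correlations(prof, features_tbl)
        assert r.loc["A", "dcm"] < 0 < r.loc["A", "path_length"]
        assert r.loc["G", "dcm"] > 0

    def test_misaligned_stimuli_rejected(self, features_tbl):
        prof = pd.DataFrame(
            [np.arange(15.0)], index=["A"], columns=[f"x{i}" for i in range(15)]
        )
        with pytest.raises(ValueError):
            ratings.rating_feature_correlations(prof, features_tbl)


class TestOls:
    def test_noiseless_profiles_recover_generating_coefficients(self, features_tbl):
        cfg = SynthConfig(residual_sd=0.0, intercept_sd=0.0, master_seed=0)
        matrix, labels, _ = gen_ratings(cfg, features_tbl)
        g = ratings.GroupAssignment(
            labels=labels, centroids=pd.DataFrame(), explained_variance=1.0
        )
        prof = ratings.group_profiles(matrix, g)
        res = ratings.ols_group_regression(prof, features_tbl)
        for grp, truth in DEFAULT_COEFFICIENTS.items():
            for term, value in truth.items():
                assert res.params.loc[grp, term] == pytest.approx(value, abs=1e-8)
            assert res.r_squared[grp] == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_gives_zero_slopes(self, features_tbl):
        prof = pd.DataFrame(
            [np.full(15, 50.0)], index=["A"], columns=features_tbl.index
        )
        res = ratings.ols_group_regression(prof, features_tbl)
        assert np.allclose(res.params.loc["A", ["width", "path_length", "dcm"]], 0.0)
        assert res.r_squared["A"] == pytest.approx(0.0, abs=1e-12)

    def test_rank_deficient_design_names_columns(self, features_tbl):
        bad = features_tbl.copy()
        bad["path_length"] = 2.0 * bad["width"] - 1.0
        prof = pd.DataFrame(
            [np.arange(15.0)], index=["A"], columns=features_tbl.index
        )
        with pytest.raises(ValueError, match="width"):
            ratings.ols_group_regression(prof, bad)

    def test_extra_noise_predictor_never_lowers_r2(self, features_tbl):
        rng = np.random.default_rng(4)
        prof = pd.DataFrame(
            [rng.uniform(20, 80, 15)], index=["A"], columns=features_tbl.index
        )
        base = ratings.ols_group_regression(prof, features_tbl)
        extended = features_tbl.copy()
        extended["noise"] = rng.normal(size=15)
        bigger = ratings.ols_group_regression(
            prof, extended, predictors=("width", "path_length", "dcm", "noise")
        )
        assert bigger.r_squared["A"] >= base.r_squared["A"] - 1e-12


def simulate_standardized_long(seed, n_raters=118, sigma2=0.6, tau00=0.08):
    """Long table on the standardized scale with known variance components."""
    rng = np.random.default_rng(seed)
    stims = [f"s{i}" for i in range(15)]
    feat = pd.DataFrame(
        rng.normal(size=(15, 3)), index=stims,
        columns=["width", "path_length", "dcm"],
    )
    thirds = n_raters // 3
    groups = pd.Series(
        ["A"] * thirds + ["L"] * thirds + ["G"] * (n_raters - 2 * thirds),
        index=[f"r{i}" for i in range(n_raters)],
    )
    betas = {
        "A": np.array([-0.075, 0.198, -0.469]),
        "L": np.array([0.352, -0.350, -0.351]),
        "G": np.array([0.071, -0.249, 0.184]),
    }
    shifts = {"A": 0.0, "L": 0.931, "G": 0.355}
    rows = []
    for rater, grp in groups.items():
        u = rng.normal(0.0, np.sqrt(tau00))
        mu = shifts[grp] + feat.to_numpy() @ betas[grp]
        y = mu + u + rng.normal(0.0, np.sqrt(sigma2), len(stims))
        rows.extend((rater, s, v) for s, v in zip(stims, y))
    long = pd.DataFrame(rows, columns=["rater_id", "stimulus_id", "rating"])
    return long, feat, groups


class TestLmm:
    def test_no_rater_heterogeneity_gives_near_zero_tau(self):
        long, feat, groups = simulate_standardized_long(seed=1, tau00=0.0)
        res = ratings.lmm_random_intercept(long, feat, groups, standardize=False)
        assert res.tau00 < 0.01

    def test_parameter_recovery_at_study_size(self):
        # single replicate: loose sanity bounds (tau00 has high sampling noise);
        # the 25% accuracy criterion lives on the replicate-averaged MAE below
        long, feat, groups = simulate_standardized_long(seed=2)
        res = ratings.lmm_random_intercept(long, feat, groups, standardize=False)
        assert res.sigma2 == pytest.approx(0.6, rel=0.25)
        assert res.tau00 == pytest.approx(0.08, rel=0.5)

    def test_recovery_mae_over_replicates(self):
        errs_s, errs_t = [], []
        for seed in range(20):
            long, feat, groups = simulate_standardized_long(seed=100 + seed)
            res = ratings.lmm_random_intercept(long, feat, groups, standardize=False)
            errs_s.append(abs(res.sigma2 - 0.6) / 0.6)
            errs_t.append(abs(res.tau00 - 0.08) / 0.08)
        assert np.mean(errs_s) < 0.25
        assert np.mean(errs_t) < 0.25

    def test_group_g_dcm_contrast_positive_on_synthetic(self, features_tbl):
        cfg = SynthConfig(residual_sd=8.0, intercept_sd=3.0, master_seed=23)
        matrix, labels, _ = gen_ratings(cfg, features_tbl)
        res = ratings.lmm_random_intercept(
            ratings.to_long(matrix), features_tbl, labels
        )
        term = "dcm:C(group, Treatment('A'))[T.G]"
        assert res.fixed_effects.loc[term, "beta"] > 0
        assert res.fixed_effects.loc["dcm", "beta"] < 0  # group A baseline

    def test_single_rater_rejected(self, features_tbl):
        long = pd.DataFrame(
            {
                "rater_id": ["r0"] * 15,
                "stimulus_id": features_tbl.index,
                "rating": np.arange(15.0),
            }
        )
        groups = pd.Series(["A"], index=["r0"])
        with pytest.raises(ValueError):
            ratings.lmm_random_intercept(long, features_tbl, groups)


class TestVarianceSummary:
    def test_published_variance_arithmetic(self):
        icc, marginal, conditional = ratings.lmm_variance_summary(
            sigma2=0.60, tau00=0.08, marginal_r2=0.322
        )
        assert icc == pytest.approx(0.118, abs=5e-4)
        assert round(icc, 2) == 0.12
        assert conditional == pytest.approx(0.401, abs=1e-3)

    def test_zero_tau_collapses_marginal_and_conditional(self):
        icc, marginal, conditional = ratings.lmm_variance_summary(
            sigma2=0.5, tau00=0.0, sigma2_fixed=0.3
        )
        assert icc == 0.0
        assert marginal == pytest.approx(conditional)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            ratings.lmm_variance_summary(sigma2=0.0, tau00=0.0, sigma2_fixed=0.1)
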