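import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radfit.io import ValidationError
from radfit.prognosis import (
    CVResult,
    covariate_associations,
    consensus_matrix,
    cv_cox,
    discover_phenotypes,
    km_dichotomize,
    likelihood_ratio_test,
    risk_scores,
    sigclust,
    zscore,
)


def _tabular_cohort(n, beta_fth=0.0, seed=0, censor=0.4):
    """Synthetic cohort table with a controllable FTH log-hazard effect."""
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 1, n)
    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "er": rng.integers(0, 2, n), "pr": rng.integers(0, 2, n),
        "her2": rng.integers(0, 2, n), "pcr": rng.integers(0, 2, n),
        "aln": rng.integers(0, 2, n),
        "tumor_size": rng.lognormal(1.0, 0.3, n),
        "suv": rng.lognormal(1.2, 0.3, n),
        "k1": rng.normal(0.12, 0.02, n).clip(0.01),
        "ki": rng.normal(0.04, 0.01, n).clip(0.001),
        "bcss_tss": z + rng.normal(0, 0.3, n),
        "phi12": z + rng.normal(0, 0.5, n),
        "phi23": rng.normal(0, 1, n),
        "phi13": z + rng.normal(0, 0.5, n),
    })
    df["fth_index"] = df[["bcss_tss", "phi12", "phi23", "phi13"]].mean(axis=1)
    df["true_z"] = beta_fth * z  # the generating log-hazard
    h0 = np.log(2) / 40.0
    t_event = rng.exponential(1.0 / (h0 * np.exp(beta_fth * z)))
    t_cens = rng.exponential(1.0 / (h0 * censor / (1 - censor)), n)
    df["rfs_time"] = np.minimum(t_event, t_cens).round(3)
    df["event"] = (t_event <= t_cens).astype(int)
    return df


class TestZscore:
    def test_hand_computation_population_sd(self):
        out = zscore(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(out["a"], [-1.224745, 0.0, 1.224745],
                                   atol=1e-6)

    def test_standardised_column_unchanged(self):
        rng = np.random.default_rng(0)
        x = rng.random(20)
        x = (x - x.mean()) / x.std(ddof=0)
        out = zscore(pd.DataFrame({"a": x}))
        np.testing.assert_allclose(out["a"], x, atol=1e-12)

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            out = zscore(pd.DataFrame({"a": [1.0, 1.0, 1.0],
                                       "b": [0.0, 1.0, 2.0]}))
        assert list(out.columns) == ["b"]


class TestCvCox:
    def test_strong_signal_recovers_high_concordance(self):
        # a single feature equal to the true log-hazard at n = 300
        df = _tabular_cohort(300, beta_fth=2.0, seed=1)
        cv = cv_cox(df, ["true_z"], seed=2)
        assert cv.mean_c > 0.8

    def test_null_features_near_half(self):
        cs = [cv_cox(_tabular_cohort(120, 0.0, seed=s), "baseline+fth",
                     seed=s).mean_c for s in range(20)]
        assert abs(np.mean(cs) - 0.5) < 0.1

    def test_deterministic(self):
        df = _tabular_cohort(90, beta_fth=1.0, seed=3)
        a = cv_cox(df, "baseline+kinetic", seed=5)
        b = cv_cox(df, "baseline+kinetic", seed=5)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_allclose(a.coefficients, b.coefficients)
        assert a.mean_c == b.mean_c

    def test_likelihood_ratio_detects_added_signal(self):
        df = _tabular_cohort(200, beta_fth=1.5, seed=4)
        base = cv_cox(df, "baseline", seed=5)
        full = cv_cox(df, "baseline+fth", seed=5)
        lr = likelihood_ratio_test(base, full)
        assert lr["dof"] == 4
        assert lr["p"] < 0.01

    def test_concordance_rank_invariant(self):
        # C depends only on the ordering of the risk scores
        from lifelines.utils import concordance_index
        df = _tabular_cohort(80, beta_fth=1.0, seed=6)
        r = np.asarray(df["bcss_tss"])
        t, e = df["rfs_time"], df["event"]
        c1 = concordance_index(t, -r, e)
        c2 = concordance_index(t, -(np.exp(r) + 5), e)
        assert c1 == pytest.approx(c2)

    def test_too_few_events_rejected(self):
        df = _tabular_cohort(30, seed=7)
        df["event"] = 0
        df.loc[:2, "event"] = 1
        with pytest.raises(ValidationError):
            cv_cox(df, "baseline", folds=3, seed=0)


class TestRiskScores:
    def _cv(self, df, feats, coefs):
        return CVResult(feature_names=feats,
                        fold_assignment=np.zeros(len(df), dtype=int),
                        coefficients=np.asarray(coefs),
                        fold_c=np.array([0.5]), mean_c=0.5,
                        full_log_likelihood=0.0, full_coefficients=None)

    def test_zero_coefficients_zero_scores(self):
        df = _tabular_cohort(20, seed=8)
        cv = self._cv(df, ["bcss_tss"], [[0.0]])
        np.testing.assert_allclose(risk_scores(df, cv, standardize=False), 0.0)

    def test_dot_product(self):
        df = _tabular_cohort(10, seed=9)
        df["bcss_tss"] = 1.5
        cv = self._cv(df, ["bcss_tss"], [[2.0]])
        np.testing.assert_allclose(risk_scores(df, cv, standardize=False), 3.0)

    def test_fold_specific_coefficients_used(self):
        df = _tabular_cohort(10, seed=10)
        df["bcss_tss"] = 1.0
        cv = self._cv(df, ["bcss_tss"], [[1.0], [10.0]])
        cv.fold_assignment = np.array([0] * 5 + [1] * 5)
        out = risk_scores(df, cv, standardize=False)
        np.testing.assert_allclose(out[:5], 1.0)
        np.testing.assert_allclose(out[5:], 10.0)


class TestKMDichotomize:
    def test_identical_groups_zero_statistic(self):
        t = np.array([5.0, 10.0, 15.0, 20.0] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        scores = np.array([0.0] * 4 + [1.0] * 4)
        res = km_dichotomize(scores, t, e, threshold=0.5)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert res["p"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        scores = np.arange(10.0)
        with pytest.raises(ValidationError):
            km_dichotomize(scores, np.ones(10), np.ones(10, int),
                           threshold=scores.max())

    def test_power_under_hazard_ratio_three(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 50
        for _ in range(reps):
            group = rng.integers(0, 2, 100)
            t_event = rng.exponential(1.0 / (0.02 * 3.0 ** group))
            t_cens = rng.uniform(10, 80, 100)
            t = np.minimum(t_event, t_cens)
            e = (t_event <= t_cens).astype(int)
            res = km_dichotomize(group + rng.normal(0, 0.01, 100), t, e)
            if res["p"] < 0.05:
                hits += 1
        assert hits / reps >= 0.8


class TestPhenotypes:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (25, 4)), rng.normal(6, 1, (25, 4))])
        res = discover_phenotypes(X, n_resample=100, n_sim=200, seed=0)
        assert res.c == 2
        assert res.sigclust_p < 0.01
        truth = np.array([0] * 25 + [1] * 25)
        agree = max(np.mean((res.phenotype - 1) == truth),
                    np.mean((res.phenotype - 1) == 1 - truth))
        assert agree == 1.0
        # ranked by mean signature index: phenotype 1 is the low group
        assert res.phenotype[:25].mean() < res.phenotype[25:].mean()

    def test_single_gaussian_null_rarely_significant(self):
        rng = np.random.default_rng(2)
        ps = [sigclust(rng.normal(0, 1, (30, 4)), n_sim=200, seed=s)["p"]
              for s in range(20)]
        assert np.mean(np.asarray(ps) > 0.05) >= 0.9

    def test_consensus_matrix_properties_and_determinism(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (20, 3))
        a = consensus_matrix(X, 2, n_resample=50, seed=4)
        b = consensus_matrix(X, 2, n_resample=50, seed=4)
        np.testing.assert_array_equal(a, b)
        assert np.allclose(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)
        assert a.min() >= 0 and a.max() <= 1

    def test_minimum_cohort_size(self):
        with pytest.raises(ValidationError):
            discover_phenotypes(np.zeros((5, 4)))


class TestCovariateAssociations:
    def test_perfect_association(self):
        rng = np.random.default_rng(4)
        ph = np.repeat([1, 2], 20)
        df = pd.DataFrame({"er": (ph == 2).astype(int),
                           "ki": rng.normal(0, 0.001, 40) + ph})
        out = covariate_associations(ph, df, categorical=["er"],
                                     continuous=["ki"]).set_index("marker")
        assert out.loc["er", "p"] < 1e-6
        assert out.loc["ki", "p"] < 1e-6

    def test_chi_square_hand_value(self):
        # 2x2 table {{10,0},{0,10}} -> chi2 = 20 without correction
        ph = np.repeat([1, 2], 10)
        df = pd.DataFrame({"er": (ph == 2).astype(int)})
        out = covariate_associations(ph, df, categorical=["er"],
                                     continuous=[])
        assert out.iloc[0]["statistic"] == pytest.approx(20.0)

    def test_null_pvalues_approximately_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(40):
            ph = rng.integers(1, 3, 60)
            df = pd.DataFrame({"ki": rng.normal(0.04, 0.01, 60)})
            out = covariate_associations(ph, df, categorical=[],
                                         continuous=["ki"])
            ps.append(out.iloc[0]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_continuous_markers_report_spread(self):
        rng = np.random.default_rng(6)
        ph = np.repeat([1, 2], 15)
        df = pd.DataFrame({"ki": rng.normal(0.04, 0.01, 30)})
        out = covariate_associations(ph, df, categorical=[], continuous=["ki"])
        assert {"iqr_ph1", "iqr_ph2", "var_ph1", "var_ph2"} <= set(out.columns)

    def test_single_phenotype_rejected(self):
        with pytest.raises(ValidationError):
            covariate_associations(np.ones(10), pd.DataFrame({"er": np.zeros(10)}))
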