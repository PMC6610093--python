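"""Group statistics: transforms, ANCOVA, corrections, correlations,
regression and the normality screen."""

import numpy as np
import pandas as pd
import pytest

import eegmst as em
from eegmst.stats import LOG_OFFSET


class TestLogTransform:
    def test_values(self):
        assert em.log_transform(1.0) == pytest.approx(0.0, abs=1e-12)
        assert em.log_transform(0.0) == pytest.approx(np.log(1e-24))
        assert em.log_transform(np.e - LOG_OFFSET) == pytest.approx(1.0)

    def test_monotone(self, rng):
        x = np.sort(rng.uniform(0, 5, size=50))
        assert np.all(np.diff(em.log_transform(x)) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            em.log_transform(-0.1)


def _hand_ancova(y, g, covs):
    """Explicit sums-of-squares oracle via normal-equation algebra."""
    n = len(y)
    X_full = np.column_stack([np.ones(n), g, *covs])
    X_red = np.column_stack([np.ones(n), *covs])

    def ssr(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    ss_error = ssr(X_full)
    ss_group = ssr(X_red) - ss_error
    df2 = n - X_full.shape[1]
    f = (ss_group / 1.0) / (ss_error / df2)
    eta = ss_group / (ss_group + ss_error)
    return f, df2, eta


class TestAncova:
    def _table(self, y, g, age, edu, iq):
        return pd.DataFrame({
            "outcome": y, "group": np.where(np.asarray(g) > 0, "SZ", "HC"),
            "age": age, "education": edu, "premorbid_iq": iq})

    def test_six_row_hand_dataset_matches_matrix_algebra(self):
        y = np.array([3.1, 2.9, 3.4, 4.2, 4.8, 4.1])
        g = np.array([0, 0, 0, 1, 1, 1])
        age = np.array([21.0, 22.0, 20.0, 23.0, 21.0, 22.0])
        table = self._table(y, g, age, np.full(6, 13.0), np.full(6, 105.0))
        # only age can enter: education and IQ are constant here
        eff = em.ancova_group_effect(table, "outcome", covariates=("age",))
        f, df2, eta = _hand_ancova(y, g, [age])
        assert eff.f == pytest.approx(f)
        assert eff.df == (1, df2)
        assert eff.eta_p_sq == pytest.approx(eta)
        assert eff.direction == 1  # SZ mean higher

    def test_identical_groups_give_null_effect(self, rng):
        y = np.tile(rng.normal(size=35), 2)
        g = np.repeat([0, 1], 35)
        table = self._table(y, g, np.tile(rng.normal(21, 2, 35), 2),
                            np.tile(rng.normal(14, 1, 35), 2),
                            np.tile(rng.normal(107, 7, 35), 2))
        eff = em.ancova_group_effect(table, "outcome")
        assert eff.f == pytest.approx(0.0, abs=1e-20)
        assert eff.eta_p_sq == pytest.approx(0.0, abs=1e-20)

    def test_denominator_df_for_70_subjects_three_covariates(self, rng):
        n = 70
        table = self._table(rng.normal(size=n), rng.integers(0, 2, n),
                            rng.normal(21, 2, n), rng.normal(14, 1, n),
                            rng.normal(107, 7, n))
        eff = em.ancova_group_effect(table, "outcome")
        assert eff.df == (1, 65)

    def test_f_invariant_to_affine_outcome_rescaling(self, rng):
        n = 40
        table = self._table(rng.normal(size=n), rng.integers(0, 2, n),
                            rng.normal(21, 2, n), rng.normal(14, 1, n),
                            rng.normal(107, 7, n))
        a = em.ancova_group_effect(table, "outcome")
        table["outcome"] = 3.0 * table["outcome"] - 7.0
        b = em.ancova_group_effect(table, "outcome")
        assert a.f == pytest.approx(b.f)
        assert a.eta_p_sq == pytest.approx(b.eta_p_sq)

    def test_collinear_covariates_rejected(self, rng):
        n = 30
        age = rng.normal(21, 2, n)
        table = self._table(rng.normal(size=n), rng.integers(0, 2, n),
                            age, 2 * age, rng.normal(107, 7, n))
        with pytest.raises(ValueError, match="rank-deficient"):
            em.ancova_group_effect(table, "outcome")

    def test_single_subject_group_rejected(self):
        table = self._table([1.0, 2.0, 3.0], [0, 0, 1],
                            [20, 21, 22], [12, 13, 14], [100, 101, 102])
        with pytest.raises(ValueError, match=">= 2 subjects"):
            em.ancova_group_effect(table, "outcome", covariates=())


class TestBonferroni:
    def test_examples(self):
        assert em.bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
        assert em.bonferroni([0.5], m=10)[0] == 1.0
        np.testing.assert_allclose(em.bonferroni([0.001, 0.02], m=8),
                                   [0.008, 0.16])

    def test_order_preserving(self, rng):
        p = rng.uniform(size=20)
        adj = em.bonferroni(p, m=40)
        # monotone in p (capping at 1 may create ties, never inversions)
        assert np.all(np.diff(adj[np.argsort(p)]) >= 0)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            em.bonferroni([0.1, 0.2, 0.3], m=2)


class TestCorrelate:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = em.correlate(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_monotone_nonlinear_spearman_one_pearson_below(self):
        x = np.linspace(1, 5, 20)
        y = np.exp(x)
        rs, _ = em.correlate(x, y, method="spearman")
        rp, _ = em.correlate(x, y, method="pearson")
        assert rs == pytest.approx(1.0)
        assert rp < 1.0

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, _ = em.correlate(x, y)
        manual = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(manual)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            em.correlate(np.ones(10), np.arange(10.0))


class TestMultipleRegression:
    def test_single_predictor_beta_equals_pearson_r(self, rng):
        n = 50
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(scale=0.8, size=n)
        table = pd.DataFrame({"y": y, "x": x})
        res = em.multiple_regression(table, "y", ("x",), controlled=())
        r, _ = em.correlate(x, y)
        assert res.beta["x"] == pytest.approx(r)

    def test_df_for_35_subjects_five_predictors(self, rng):
        n = 35
        cols = {f"x{k}": rng.normal(size=n) for k in range(2)}
        cols.update(duration_of_illness=rng.normal(12, 5, n),
                    dup=rng.normal(5, 4, n),
                    risperidone_equivalent=rng.normal(4, 1.5, n))
        cols["y"] = rng.normal(size=n)
        res = em.multiple_regression(pd.DataFrame(cols), "y", ("x0", "x1"))
        assert res.df == (5, 29)

    def test_planted_dominant_predictor_recovered(self):
        preset = em.CohortPreset(
            n_per_group=2000,
            variables={"SZ": {"bc_posterior_gamma": (0.14, 0.03),
                              "tau": (674.0, 333.0),
                              "bc_max_beta": (0.5, 0.1)},
                       "HC": {"bc_posterior_gamma": (0.09, 0.03),
                              "tau": (455.0, 144.0),
                              "bc_max_beta": (0.45, 0.1)}},
            corr_variables=("bc_posterior_gamma", "tau"),
            cross_correlations=np.array([[1.0, 0.72], [0.72, 1.0]]))
        table = em.generate_cohort(preset, seed=31)
        sz = table[table.group == "SZ"]
        res = em.multiple_regression(
            sz, "tau", ("bc_posterior_gamma", "bc_max_beta"))
        assert res.beta["bc_posterior_gamma"] == pytest.approx(0.72, abs=0.05)
        assert abs(res.beta["bc_max_beta"]) < 0.1
        assert max(res.beta, key=lambda k: abs(res.beta[k])) == \
            "bc_posterior_gamma"

    def test_collinear_columns_named(self, rng):
        n = 40
        x = rng.normal(size=n)
        table = pd.DataFrame({"y": rng.normal(size=n), "a": x, "b": x})
        with pytest.raises(ValueError, match="'a', 'b'"):
            em.multiple_regression(table, "y", ("a", "b"), controlled=())


class TestKsNormality:
    def test_normal_sample_passes(self, rng):
        d, p = em.ks_normality(rng.normal(size=2000))
        assert p > 0.1

    def test_exponential_sample_fails(self, rng):
        _, p = em.ks_normality(rng.exponential(size=2000))
        assert p < 0.01

    def test_statistic_matches_empirical_cdf_gap(self, rng):
        from scipy import stats as sps
        x = np.sort(rng.normal(size=20))
        d, _ = em.ks_normality(x)
        cdf = sps.norm.cdf(x, x.mean(), x.std(ddof=1))
        ranks = np.arange(1, 21)
        gap = max(np.max(ranks / 20 - cdf), np.max(cdf - (ranks - 1) / 20))
        assert d == pytest.approx(gap)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            em.ks_normality(np.ones(10))
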