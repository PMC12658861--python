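"""ANCOVA association and PLS/PLS-DA latent-variable models."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metabokit.feature_table import FeatureTable
from metabokit.stats import (ancova, cross_validate, dual_filter, pls_fit,
                             residualize, vip)
from metabokit.synthetic import SimulationSpec, simulate_feature_table


def _table(arr, meta):
    arr = np.asarray(arr, dtype=float)
    values = pd.DataFrame(arr, index=[f"f{i}" for i in range(arr.shape[0])],
                          columns=[f"s{j}" for j in range(arr.shape[1])])
    meta = pd.DataFrame(meta, index=values.columns)
    return FeatureTable(values, meta)


class TestAncova:
    def test_matches_pooled_t_test(self):
        """With two groups and no covariates the trait t equals the
        pooled-variance two-sample t statistic."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=16)
        groups = ["a"] * 8 + ["b"] * 8
        t = _table([y], {"group": groups})
        res = ancova(t, "group")
        t_ref, p_ref = sps.ttest_ind(y[8:], y[:8], equal_var=True)
        assert res.table.iloc[0]["t"] == pytest.approx(t_ref, abs=1e-10)
        assert res.table.iloc[0]["p"] == pytest.approx(p_ref, abs=1e-10)
        assert res.table.iloc[0]["beta"] == pytest.approx(
            y[8:].mean() - y[:8].mean(), abs=1e-10)

    def test_null_p_values_uniform(self):
        """Trait orthogonal to all features: p-values follow U(0,1)."""
        rng = np.random.default_rng(1)
        n_feat, n = 2000, 40
        arr = rng.normal(size=(n_feat, n))
        groups = ["a"] * (n // 2) + ["b"] * (n // 2)
        res = ancova(_table(arr, {"group": groups}), "group")
        stat = sps.kstest(res.table["p"], "uniform").statistic
        assert stat < 0.05

    def test_collinear_covariate_skipped(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(2, 10))
        g = [0.0] * 5 + [1.0] * 5
        t = _table(arr, {"group": g, "dup": g})
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = ancova(t, "group", ["dup"])
        assert len(res.skipped) == 2

    def test_beta_recovery_unbiased(self):
        """Planted group effect is recovered without bias (mean error
        < 5% of delta over replicates)."""
        errs = []
        for seed in range(40):
            spec = SimulationSpec(seed=seed, n_per_group=30, n_features=10,
                                  n_planted=10, delta=2.0,
                                  missing_rate=0.0, zero_rate=0.0)
            table, truth = simulate_feature_table(spec)
            res = ancova(table, "group", ["age", "ancestry"])
            errs.append(res.table["beta"].mean() - truth["delta"])
        assert abs(np.mean(errs)) < 0.05 * 2.0

    def test_residuals_mean_zero(self, small_table):
        res = ancova(small_table, "group")
        for fid in res.residuals.index:
            r = res.residuals.loc[fid].dropna()
            if len(r):
                assert r.mean() == pytest.approx(0.0, abs=1e-10)


class TestResidualize:
    def test_zero_covariate_effect_equals_centering(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(size=(3, 12))
        cov = rng.normal(size=12)
        # feature independent of covariate in expectation; compare to the
        # exact OLS result, which equals centering when slope is ~0 —
        # instead assert the orthogonality identity which is exact
        t = _table(arr, {"group": ["a"] * 6 + ["b"] * 6, "age": cov})
        out = residualize(t, ["age"])
        for i in range(3):
            r = out.values.iloc[i].to_numpy()
            assert float(r @ cov) == pytest.approx(0.0, abs=1e-8)
            assert r.mean() == pytest.approx(0.0, abs=1e-10)

    def test_constant_feature_zero_residuals(self):
        t = _table([[4.0] * 8], {"group": ["a"] * 4 + ["b"] * 4,
                                 "age": np.arange(8.0)})
        out = residualize(t, ["age"])
        np.testing.assert_allclose(out.values.iloc[0], 0.0, atol=1e-12)


class TestPls:
    def test_exact_linear_fit_r2y_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        m = pls_fit(X, y, n_components=3)
        assert m.r2y == pytest.approx(1.0, abs=1e-10)

    def test_first_score_is_x_times_unit_weight(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        m = pls_fit(X, y, n_components=2)
        w1 = m.weights[:, 0]
        assert np.linalg.norm(w1) == pytest.approx(1.0, abs=1e-10)
        Xs = (X - m.x_mean) / m.x_std
        np.testing.assert_allclose(m.scores[:, 0], Xs @ w1, atol=1e-8)

    def test_matches_sklearn_on_toy_matrix(self):
        """Independent-algorithm oracle: scikit-learn's SVD-based PLS on a
        5 x 4 toy problem agrees with NIPALS up to sign."""
        from sklearn.cross_decomposition import PLSRegression
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 4))
        y = rng.normal(size=(5, 1))
        m = pls_fit(X, y, n_components=2)
        sk = PLSRegression(n_components=2, scale=True).fit(X, y)
        for a in range(2):
            ours, theirs = m.scores[:, a], sk.x_scores_[:, a]
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)
        np.testing.assert_allclose(m.predict(X), sk.predict(X), atol=1e-8)

    def test_equals_ols_on_orthonormal_x_at_full_rank(self):
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 4)))
        y = rng.normal(size=12)
        m = pls_fit(Q, y, n_components=4, scale=False)
        Xc = Q - Q.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        np.testing.assert_allclose(m.predict(Q), (Xc @ beta + y.mean())[:, None],
                                   atol=1e-8)

    def test_zero_variance_predictor_dropped(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            m = pls_fit(X, y, n_components=1)
        assert m.predictor_names == ["x1"]

    def test_too_many_components_truncated(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="rank"):
            m = pls_fit(X, y, n_components=5)
        assert m.n_components <= 2


class TestCrossValidation:
    def test_noiseless_linear_q2_is_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([2.0, -1.0, 0.5])
        for folds in (3, 7):
            q2, _ = cross_validate(X, y, n_components=3, folds=folds, seed=0)
            assert q2 == pytest.approx(1.0, abs=1e-8)

    def test_null_q2_not_positive(self):
        """Y independent of X: Q2Y <= 0 in at least 90% of replicates."""
        neg = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 10))
            y = rng.normal(size=40)
            q2, _ = cross_validate(X, y, n_components=2, folds=7, seed=seed)
            neg += q2 <= 0
        assert neg >= 0.9 * reps

    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(24, 5))
        y = np.array(["a", "b"] * 12)
        a = cross_validate(X, y, folds=7, seed=3)
        b = cross_validate(X, y, folds=7, seed=3)
        assert a == b

    def test_q2_below_r2(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.normal(size=(30, 6))
            y = X[:, 0] + r.normal(size=30)
            m = pls_fit(X, y, n_components=2)
            q2, _ = cross_validate(X, y, n_components=2, folds=7, seed=seed)
            assert q2 <= m.r2y + 1e-8

    def test_rmsee_denominator(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(20, 3))
        y = X[:, 0] + 0.1 * rng.normal(size=20)
        m = pls_fit(X, y, n_components=2)
        _, rmsee = cross_validate(X, y, n_components=2, folds=5, seed=0)
        resid = y[:, None] - m.predict(X)
        expect = np.sqrt((resid ** 2).sum() / (20 - 2 - 1))
        assert rmsee == pytest.approx(expect, abs=1e-10)


class TestVip:
    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(25, 8))
        y = X[:, 2] + rng.normal(size=25)
        m = pls_fit(X, y, n_components=3)
        v = vip(m)
        assert float((v ** 2).sum()) == pytest.approx(8.0, abs=1e-8)

    def test_relevant_predictor_has_max_vip(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 6))
            y = 2.0 * X[:, 3] + 0.3 * rng.normal(size=30)
            m = pls_fit(X, y, n_components=2)
            hits += int(np.argmax(vip(m))) == 3
        assert hits == 50

    def test_single_component_equal_weights_all_one(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.001]])
        y = X.sum(axis=1)
        m = pls_fit(X, y, n_components=1)
        np.testing.assert_allclose(vip(m), 1.0, atol=1e-3)


class TestDualFilter:
    def _fake_results(self, pvals):
        tab = pd.DataFrame({"p": pvals, "p_fdr": pvals},
                           index=[f"f{i}" for i in range(len(pvals))])
        from metabokit.stats import AncovaResults
        return AncovaResults(tab, pd.DataFrame(), "group")

    def test_topk_universe_reduces_to_fdr(self):
        res = self._fake_results([0.01, 0.2, 0.001, 0.8])
        v = pd.Series([1.0, 2.0, 3.0, 4.0], index=res.table.index)
        assert dual_filter(res, v, 0.05, top_k=4) == ["f0", "f2"]

    def test_pmax_one_reduces_to_topk(self):
        res = self._fake_results([0.5, 0.6, 0.7, 0.8])
        v = pd.Series([4.0, 3.0, 2.0, 1.0], index=res.table.index)
        assert dual_filter(res, v, p_fdr_max=1.01, top_k=2) == ["f0", "f1"]

    def test_exact_intersection(self):
        res = self._fake_results([0.01, 0.01, 0.01, 0.9, 0.9, 0.9])
        v = pd.Series([9, 8, 1, 7, 6, 2.0], index=res.table.index)
        # top-4 VIP = f0,f1,f3,f4; FDR-pass = f0,f1,f2 -> intersection f0,f1
        assert dual_filter(res, v, 0.05, top_k=4) == ["f0", "f1"]

    def test_empty_intersection_warns(self):
        res = self._fake_results([0.9, 0.9])
        v = pd.Series([1.0, 2.0], index=res.table.index)
        with pytest.warns(UserWarning):
            assert dual_filter(res, v, 0.05, top_k=1) == []
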