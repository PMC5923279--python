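"""NIPALS PLS regression, VIP, cross-validation, CV-ANOVA and selection."""

import numpy as np
import pandas as pd
import pytest

from metadigest import pls as mpls
from metadigest.simulate import SyntheticConfig, generate_dataset, generate_null_dataset
from tests.conftest import SERUM_ONLY, make_serum


def eigen_pls_oracle(X, y, A):
    """Independent per-component oracle: the NIPALS weight maximizes
    cov(Xw, y), i.e. w is the leading eigenvector of Xᵀy yᵀX on the current
    residuals; scores/loadings follow, with the same deflation."""
    Xs, _, _, _ = mpls.autoscale(X)
    ys = (y - y.mean()) / y.std(ddof=1)
    E, f = Xs.copy(), ys.copy()
    Ws, Ts, Ps, cs = [], [], [], []
    for _ in range(A):
        M = np.outer(E.T @ f, E.T @ f)  # Xᵀy yᵀX
        lam, vec = np.linalg.eigh(M)
        w = vec[:, -1]
        t = E @ w
        p = E.T @ t / (t @ t)
        c = f @ t / (t @ t)
        E = E - np.outer(t, p)
        f = f - c * t
        Ws.append(w), Ts.append(t), Ps.append(p), cs.append(c)
    return (np.array(Ws).T, np.array(Ts).T, np.array(Ps).T, np.array(cs))


class TestFitPls:
    def test_single_variable_equals_least_squares(self, rng):
        x = rng.standard_normal(25)
        y = 3 * x + rng.standard_normal(25)
        m = mpls.fit_pls(x[:, None], y, A=1)
        slope, intercept = np.polyfit(x, y, 1)
        assert np.allclose(m.predict(x[:, None]), slope * x + intercept,
                           atol=1e-10)

    def test_full_rank_matches_ols_r2(self, rng):
        X = rng.standard_normal((20, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(20)
        m = mpls.fit_pls(X, y, A=5)
        # OLS oracle
        Z = np.column_stack([np.ones(20), X])
        resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        r2_ols = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert m.r2y == pytest.approx(r2_ols, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_eigendecomposition_oracle(self, seed):
        g = np.random.default_rng(seed)
        X = g.standard_normal((12, 5))
        y = g.standard_normal(12)
        m = mpls.fit_pls(X, y, A=3)
        W, T, P, c = eigen_pls_oracle(X, y, 3)
        for a in range(3):
            sign = np.sign(W[:, a] @ m.weights[:, a])
            assert np.allclose(m.weights[:, a], sign * W[:, a], atol=1e-8)
            assert np.allclose(m.scores[:, a], sign * T[:, a], atol=1e-8)
            assert np.allclose(m.loadings[:, a], sign * P[:, a], atol=1e-8)

    def test_predictions_match_sklearn(self, rng):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.standard_normal((30, 8))
        y = X[:, 0] - 2 * X[:, 3] + 0.3 * rng.standard_normal(30)
        ours = mpls.fit_pls(X, y, A=3).predict(X)
        ref = sklearn_pls.PLSRegression(n_components=3, scale=True).fit(X, y)
        assert np.allclose(ours, ref.predict(X).ravel(), atol=1e-8)

    def test_score_orthogonality_and_r2_monotone(self, serum_dataset):
        X = serum_dataset.buckets["serum"].data
        y = serum_dataset.traits.data["AMEn"].to_numpy()
        m = mpls.fit_pls(X, y, A=4)
        G = m.scores.T @ m.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.trace(G)
        assert np.all(np.diff(m.r2y_cum) >= -1e-12)
        assert 0.0 <= m.r2y <= 1.0

    def test_a1_coefficient_proportional_to_xty(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        m = mpls.fit_pls(X, y, A=1)
        Xs, *_ = mpls.autoscale(X)
        ys = (y - y.mean()) / y.std(ddof=1)
        direction = Xs.T @ ys
        cos = (m.b_scaled @ direction) / (
            np.linalg.norm(m.b_scaled) * np.linalg.norm(direction))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError):
            mpls.fit_pls(rng.standard_normal((10, 3)), np.ones(10), A=1)


class TestVip:
    def test_equal_weights_give_unit_vip(self, rng):
        # orthonormal centered X columns with y = their sum: equal weights
        G = rng.standard_normal((32, 4))
        Q, _ = np.linalg.qr(G - G.mean(axis=0))
        y = Q.sum(axis=1)
        m = mpls.fit_pls(Q, y, A=1)
        assert np.allclose(mpls.vip(m), 1.0, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_mean_square_is_exactly_one(self, seed):
        g = np.random.default_rng(seed)
        X = g.standard_normal((25, 9))
        y = X[:, 0] + g.standard_normal(25)
        m = mpls.fit_pls(X, y, A=3)
        assert np.mean(mpls.vip(m) ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_informative_buckets_outrank_noise(self, serum_dataset):
        X = serum_dataset.buckets["serum"].data
        y = serum_dataset.traits.data["AMEn"].to_numpy()
        m = mpls.fit_pls(X, y, A=2)
        v = pd.Series(mpls.vip(m), index=X.columns)
        inf = serum_dataset.informative["serum"]
        noise_median = v.drop(inf).median()
        assert (v[inf] > noise_median).all()


class TestCrossValidation:
    def test_folds_deterministic_venetian(self):
        folds = mpls.venetian_folds(10, 3)
        assert [f.tolist() for f in folds] == [[0, 3, 6, 9], [1, 4, 7], [2, 5, 8]]

    def test_noiseless_linear_q2_near_one(self, rng):
        X = rng.standard_normal((40, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        rep = mpls.cross_validate(X, y, A=5, K=7)
        assert rep.q2 > 0.99

    def test_rmsee_below_rmsecv_on_planted_data(self):
        below = sum(
            (lambda r: r.rmsee <= r.rmsecv)(
                mpls.cross_validate(
                    make_serum(seed).buckets["serum"].data,
                    make_serum(seed).traits.data["AMEn"].to_numpy(), 2, 7))
            for seed in range(10))
        assert below >= 9

    def test_q2_not_above_r2y(self, serum_dataset):
        X = serum_dataset.buckets["serum"].data
        y = serum_dataset.traits.data["AMEn"].to_numpy()
        m = mpls.fit_pls(X, y, A=2)
        rep = mpls.cross_validate(X, y, A=2, K=7)
        assert rep.q2 <= m.r2y

    def test_small_fold_error(self, rng):
        with pytest.raises(ValueError):
            mpls.cross_validate(rng.standard_normal((10, 4)),
                                rng.standard_normal(10), A=1, K=7)

    def test_jackknife_ci_brackets_strong_coefficient(self, serum_dataset):
        X = serum_dataset.buckets["serum"].data
        y = serum_dataset.traits.data["AMEn"].to_numpy()
        rep = mpls.cross_validate(X, y, A=2, K=7)
        tab = rep.coefficient_table()
        inf = serum_dataset.informative["serum"]
        # planted serum buckets load negatively and significantly
        assert (tab.loc[inf, "ci_upper"] < 0).all()


class TestCvAnova:
    def test_press_equal_ssy_is_null_result(self, rng):
        rep = mpls.cross_validate(rng.standard_normal((30, 4)),
                                  rng.standard_normal(30), A=2, K=5)
        rep.press_per_component = np.array([rep.ss_y, rep.ss_y])
        res = mpls.cv_anova(rep)
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_planted_signal_strongly_significant(self):
        sig = sum(mpls.cv_anova(mpls.cross_validate(
            (ds := make_serum(seed)).buckets["serum"].data,
            ds.traits.data["AMEn"].to_numpy(), 2, 7)).p_value < 0.01
            for seed in range(10))
        assert sig >= 9

    def test_dof_error(self, rng):
        rep = mpls.cross_validate(rng.standard_normal((14, 4)),
                                  rng.standard_normal(14), A=2, K=7)
        rep.n = 3
        with pytest.raises(ValueError):
            mpls.cv_anova(rep)


class TestIterativeSelection:
    def test_exact_duplicates_stop_without_removal(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame(np.tile(x[:, None], (1, 6)),
                         columns=[f"d{j}" for j in range(6)])
        y = x + 0.1 * rng.standard_normal(30)
        trace, _ = mpls.iterative_selection(X, y, A=1, K=5)
        # identical columns share identical VIP = 1: nothing qualifies
        assert len(trace.iterations) == 1
        assert trace.iterations[0].removed == {}

    def test_variable_sets_strictly_shrink(self, serum_dataset):
        X = serum_dataset.buckets["serum"].data
        y = serum_dataset.traits.data["AMEn"].to_numpy()
        trace, _ = mpls.iterative_selection(X, y, A=2, K=7)
        sizes = [len(it.variables) for it in trace.iterations]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_selection_does_not_damage_prediction(self):
        for seed in range(10):
            ds = make_serum(seed)
            X = ds.buckets["serum"].data
            y = ds.traits.data["AMEn"].to_numpy()
            trace, _ = mpls.iterative_selection(X, y, A=2, K=7)
            assert trace.best.q2 >= trace.iterations[0].q2 - 0.02

    def test_recovers_planted_biomarkers_typically(self):
        # small-scale recovery check; the 50-seed criterion lives in the
        # acceptance suite
        tp_total = fp_total = 0
        for seed in range(10):
            ds = make_serum(seed)
            trace, _ = mpls.iterative_selection(
                ds.buckets["serum"].data,
                ds.traits.data["AMEn"].to_numpy(), A=2, K=7)
            sel = set(trace.best.variables)
            inf = set(ds.informative["serum"])
            tp_total += len(sel & inf)
            fp_total += len(sel - inf)
        assert tp_total >= 7 * 10  # nearly all informative retained
        assert fp_total <= 5 * 10  # noise kept well below panel size

    def test_needs_at_least_four_variables(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)))
        with pytest.raises(ValueError):
            mpls.iterative_selection(X, rng.standard_normal(20))


class TestNullBehaviour:
    def test_null_q2_and_cvanova(self):
        # 15-seed spot check of the null calibration (full version in the
        # acceptance suite)
        q2_ok = p_sig = 0
        for seed in range(15):
            ds = generate_null_dataset(SyntheticConfig(seed=seed, **SERUM_ONLY))
            rep = mpls.cross_validate(ds.buckets["serum"].data,
                                      ds.traits.data["AMEn"].to_numpy(), 2, 7)
            q2_ok += rep.q2 <= 0.05
            p_sig += mpls.cv_anova(rep).p_value < 0.05
        assert q2_ok >= 13
        assert p_sig <= 2
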