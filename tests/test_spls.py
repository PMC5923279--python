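"""Canonical-mode sparse PLS, the keep-quarter rule and similarity scores."""

import numpy as np
import pandas as pd
import pytest

from metadigest import spls as mspls
from metadigest.simulate import SPLS_TRAITS, SyntheticConfig, generate_dataset
from tests.conftest import SERUM_ONLY, make_serum


class TestKeepQuarter:
    @pytest.mark.parametrize("p,expected", [
        (191, 48), (160, 40), (64, 16),   # the study's three block sizes
        (4, 1), (6, 2),                    # .5 rounds up
    ])
    def test_rule(self, p, expected):
        assert mspls.keep_quarter(p) == expected

    def test_tiny_block_warns(self):
        with pytest.warns(UserWarning):
            assert mspls.keep_quarter(3) == 1


def spls_traits_block(ds):
    return ds.traits.data[list(SPLS_TRAITS)]


class TestFitSplsCanonical:
    def test_dense_limit_equals_svd_of_cross_covariance(self, rng):
        X = rng.standard_normal((30, 10))
        Y = rng.standard_normal((30, 4))
        m = mspls.fit_spls_canonical(X, Y, H=1, keep_x=10, keep_y=4)
        Xs, *_ = mspls.autoscale_matrix(np.asarray(X, float))
        Ys, *_ = mspls.autoscale_matrix(np.asarray(Y, float))
        U, s, Vt = np.linalg.svd(Xs.T @ Ys, full_matrices=False)
        sign = np.sign(U[:, 0] @ m.x_loadings[:, 0])
        assert np.allclose(m.x_loadings[:, 0], sign * U[:, 0], atol=1e-8)
        assert np.allclose(m.y_loadings[:, 0], sign * Vt[0], atol=1e-8)

    @pytest.mark.parametrize("keep", [1, 3, 7, 16])
    def test_exact_cardinality(self, rng, keep):
        X = rng.standard_normal((25, 16))
        Y = rng.standard_normal((25, 4))
        m = mspls.fit_spls_canonical(X, Y, H=2, keep_x=keep)
        for h in range(2):
            assert np.count_nonzero(m.x_loadings[:, h]) == keep
            assert np.linalg.norm(m.x_loadings[:, h]) == pytest.approx(1.0,
                                                                       abs=1e-10)
            assert np.linalg.norm(m.y_loadings[:, h]) == pytest.approx(1.0,
                                                                       abs=1e-10)

    def test_sign_convention_largest_entry_positive(self, serum_dataset):
        m = mspls.fit_spls_canonical(serum_dataset.buckets["serum"].data,
                                     spls_traits_block(serum_dataset),
                                     H=2, keep_x=16)
        for h in range(2):
            u = m.x_loadings[:, h]
            assert u[np.argmax(np.abs(u))] > 0

    def test_deflation_strictly_reduces_x_norm(self, serum_dataset):
        X = serum_dataset.buckets["serum"].data
        Y = spls_traits_block(serum_dataset)
        m = mspls.fit_spls_canonical(X, Y, H=2, keep_x=16)
        # reconstruct the deflation path and watch the Frobenius norm
        Ex = m.x_scaled.copy()
        norms = [np.linalg.norm(Ex)]
        for h in range(2):
            xi = m.x_scores[:, h]
            Ex = Ex - np.outer(xi, xi @ Ex) / (xi @ xi)
            norms.append(np.linalg.norm(Ex))
        assert norms[0] > norms[1] > norms[2]

    def test_recovers_planted_support_and_signs(self):
        ok = 0
        for seed in range(10):
            ds = make_serum(seed, noise_sd=0.2)
            m = mspls.fit_spls_canonical(ds.buckets["serum"].data,
                                         spls_traits_block(ds), H=2, keep_x=16)
            inf = set(ds.informative["serum"])
            support = set(m.selected(1))
            names = m.x_names
            u = m.x_loadings[:, 0]
            # orient the component so AMEn loads positively
            orient = np.sign(m.y_loadings[list(SPLS_TRAITS).index("AMEn"), 0])
            signs_ok = all(
                np.sign(u[names.index(b)]) * orient == -1.0  # serum sign
                for b in support & inf)
            if len(support & inf) >= 8 and signs_ok:
                ok += 1
        assert ok >= 8


class TestExplainedVariance:
    def test_rank_one_noise_free_y_fully_explained(self, rng):
        t = rng.standard_normal(50)
        X = pd.DataFrame(0.8 * np.outer(t, np.array([-1, -1, 1, 1, -1]))
                         + 0.2 * rng.standard_normal((50, 5)))
        Y = pd.DataFrame(np.outer(t, [0.9, 0.7, 0.85, 0.8]))
        m = mspls.fit_spls_canonical(X, Y, H=1, keep_x=5)
        assert m.y_explained[0] == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_score_explains_nothing(self, rng):
        block = rng.standard_normal((40, 5))
        block -= block.mean(axis=0)
        score = rng.standard_normal(40)
        score -= score.mean()
        block -= np.outer(score, score @ block) / (score @ score)
        assert mspls.explained_variance(block, score)[0] == pytest.approx(
            0.0, abs=1e-12)

    def test_planted_regime_matches_study_scale(self):
        vals = [mspls.fit_spls_canonical(
            (ds := make_serum(seed)).buckets["serum"].data,
            spls_traits_block(ds), H=2, keep_x=16).y_explained[0]
            for seed in range(10)]
        assert all(0.6 <= v <= 0.95 for v in vals)


class TestSimilarityMatrix:
    def test_bounded_by_one_in_magnitude(self, serum_dataset):
        m = mspls.fit_spls_canonical(serum_dataset.buckets["serum"].data,
                                     spls_traits_block(serum_dataset),
                                     H=2, keep_x=16)
        sim = mspls.similarity_matrix(m)
        assert (sim.values.abs().values <= 1.0 + 1e-12).all()
        assert sim.values.shape == (16, 4)  # selected buckets x traits

    def test_rank_one_limit_equals_direct_correlation(self, rng):
        # noise-free rank-1 blocks: similarity reduces to cor(X_j, Y_k) = ±1
        t = rng.standard_normal(40)
        X = pd.DataFrame({f"b{j}": a * t for j, a in
                          enumerate([-0.8, -0.5, 1.2, 0.3, -2.0, 0.9])})
        Y = pd.DataFrame({f"y{k}": q * t for k, q in
                          enumerate([0.9, 0.7, 0.85, -0.8])})
        m = mspls.fit_spls_canonical(X, Y, H=1, keep_x=6)
        sim = mspls.similarity_matrix(m).values
        direct = np.corrcoef(X.T.values, Y.T.values)[:6, 6:]
        assert np.allclose(sim.values, direct, atol=1e-6)

    def test_bucket_orthogonal_to_score_gives_zero_row(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"inf": x, "orth": np.nan})
        o = rng.standard_normal(50)
        o -= (o @ (x - x.mean())) / ((x - x.mean()) @ (x - x.mean())) * (x - x.mean())
        o -= o.mean()
        X["orth"] = o
        Y = pd.DataFrame({"y1": x * 2, "y2": -x})
        m = mspls.fit_spls_canonical(X, Y, H=1, keep_x=2)
        sim = mspls.similarity_matrix(m)
        # score is exactly along x; the orthogonalized bucket decorrelates
        assert np.allclose(sim.values.loc["orth"].values, 0.0, atol=1e-8)
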