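"""PCA, OPLS-DA, multi-class PLS-DA, and VIP scores."""

import numpy as np
import pytest

from metabomark import (
    auto_orthogonal,
    compute_vip,
    cross_validate_q2,
    fit_oplsda,
    fit_pca,
    fit_plsda_multiclass,
    ModelSpec,
)
from metabomark.chemometrics import dummy_matrix


def _centre(x):
    return x - x.mean(axis=0)


class TestPca:
    def test_rank_one_matrix_fully_explained(self, rng):
        X = np.outer(rng.normal(size=12), rng.normal(size=6))
        m = fit_pca(_centre(X), 1)
        assert m.r2x_cum == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_error_matches_unexplained_ss(self, rng):
        X = _centre(rng.normal(size=(25, 10)))
        A = 3
        m = fit_pca(X, A)
        recon = m.scores @ m.loadings.T
        resid_ss = float(((X - recon) ** 2).sum())
        total_ss = float((X**2).sum())
        assert resid_ss == pytest.approx(total_ss * (1 - m.r2x_cum), rel=1e-9)

    def test_component_shares_non_increasing(self, rng):
        X = _centre(rng.normal(size=(30, 8)))
        m = fit_pca(X, 5)
        assert np.all(np.diff(m.r2x_per_component) <= 1e-12)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(rng.normal(size=(5, 3)), 5)


class TestOplsda:
    def test_separated_clusters_give_high_r2y(self, two_group_scaled):
        X, g = two_group_scaled
        m = fit_oplsda(X, g, n_orthogonal=0)
        assert m.r2y > 0.9
        assert m.n_predictive == 1

    def test_zero_orthogonal_matches_one_component_pls(self, two_group_scaled):
        from sklearn.cross_decomposition import PLSRegression

        X, g = two_group_scaled
        m = fit_oplsda(X, g, n_orthogonal=0)
        y, _, _ = dummy_matrix(g)
        ref = PLSRegression(n_components=1, scale=False).fit(X, y)
        t_ref = ref.x_scores_[:, 0]
        t = m.predictive_scores[:, 0]
        sign = np.sign(t @ t_ref) or 1.0
        np.testing.assert_allclose(t, sign * t_ref, atol=1e-8)

    def test_permuted_labels_fall_in_chance_distribution(self, rng):
        # structureless X: r2y of one shuffled fit sits inside the brute-force
        # distribution of 200 refits under further shuffles
        X = _centre(rng.normal(size=(30, 12)))
        g = np.array(["a"] * 15 + ["b"] * 15)
        obs = fit_oplsda(X, rng.permutation(g), n_orthogonal=0).r2y
        dist = np.array([
            fit_oplsda(X, rng.permutation(g), n_orthogonal=0).r2y for _ in range(200)
        ])
        lo, hi = np.quantile(dist, [0.005, 0.995])
        assert lo <= obs <= hi

    def test_orthogonal_scores_uncorrelated_with_dummy(self, rng):
        X = _centre(rng.normal(size=(40, 20)))
        X[:20, :5] += 2.0
        g = np.array(["a"] * 20 + ["b"] * 20)
        m = fit_oplsda(X, g, n_orthogonal=3)
        y, _, _ = dummy_matrix(g)
        for k in range(m.n_orthogonal):
            t_o = m.orthogonal_scores[:, k]
            corr = abs(t_o @ y[:, 0]) / (np.linalg.norm(t_o) * np.linalg.norm(y[:, 0]))
            assert corr < 1e-8

    def test_score_blocks_mutually_orthogonal(self, rng):
        X = _centre(rng.normal(size=(30, 15)))
        X[:15, 0] += 3
        g = np.array(["a"] * 15 + ["b"] * 15)
        m = fit_oplsda(X, g, n_orthogonal=2)
        t = m.predictive_scores[:, 0]
        for k in range(m.n_orthogonal):
            t_o = m.orthogonal_scores[:, k]
            assert abs(t @ t_o) < 1e-8 * np.linalg.norm(t) * np.linalg.norm(t_o)

    def test_ss_conservation(self, rng):
        X = _centre(rng.normal(size=(25, 10)))
        X[:12, 1] += 2
        g = np.array(["a"] * 12 + ["b"] * 13)
        m = fit_oplsda(X, g, n_orthogonal=2)
        recon = m.predictive_scores @ m.predictive_loadings.T
        recon += m.orthogonal_scores @ m.orthogonal_loadings.T
        resid = X - recon
        total = float((X**2).sum())
        assert float((recon**2).sum()) + float((resid**2).sum()) == pytest.approx(
            total, rel=1e-8
        )
        assert m.r2x == pytest.approx(float((recon**2).sum()) / total, rel=1e-8)

    def test_label_swap_flips_scores_only(self, two_group_scaled):
        X, g = two_group_scaled
        swapped = np.where(g == "case", "control", "case")
        m1 = fit_oplsda(X, g, n_orthogonal=1)
        m2 = fit_oplsda(X, swapped, n_orthogonal=1)
        np.testing.assert_allclose(
            m1.predictive_scores, -m2.predictive_scores, atol=1e-10
        )
        assert m1.r2x == pytest.approx(m2.r2x, rel=1e-12)
        assert m1.r2y == pytest.approx(m2.r2y, rel=1e-12)
        np.testing.assert_allclose(
            compute_vip(m1).vip.to_numpy(), compute_vip(m2).vip.to_numpy(), atol=1e-10
        )

    def test_scale_equivariance(self, two_group_scaled):
        X, g = two_group_scaled
        m1 = fit_oplsda(X, g, n_orthogonal=1)
        m2 = fit_oplsda(3.7 * X, g, n_orthogonal=1)
        assert m1.r2x == pytest.approx(m2.r2x, rel=1e-10)
        assert m1.r2y == pytest.approx(m2.r2y, rel=1e-10)
        np.testing.assert_allclose(
            compute_vip(m1).vip.to_numpy(), compute_vip(m2).vip.to_numpy(), atol=1e-10
        )

    def test_small_class_and_multiclass_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            fit_oplsda(X, ["a"] + ["b"] * 9)
        with pytest.raises(ValueError, match="multiclass"):
            fit_oplsda(X, ["a", "a", "a", "b", "b", "b", "c", "c", "c", "c"])


class TestPlsdaMulticlass:
    @staticmethod
    def _three_groups(rng, n=20, p=12, shift=5.0):
        X = rng.normal(size=(3 * n, p))
        X[:n, 0] += shift
        X[n: 2 * n, 1] += shift
        X[2 * n:, 2] += shift
        g = np.array(["a"] * n + ["b"] * n + ["c"] * n)
        return _centre(X), g

    def test_displaced_groups_give_high_r2y(self, rng):
        X, g = self._three_groups(rng)
        m = fit_plsda_multiclass(X, g, n_components=2)
        assert m.r2y > 0.8
        assert m.kind == "plsda"
        assert m.n_orthogonal == 0

    def test_explained_y_grows_with_components(self, rng):
        X, g = self._three_groups(rng)
        r1 = fit_plsda_multiclass(X, g, n_components=1).r2y
        r2 = fit_plsda_multiclass(X, g, n_components=2).r2y
        assert r1 < r2

    def test_single_feature_fully_explained_in_one_component(self, rng):
        x = np.concatenate([rng.normal(0, 1, 6), rng.normal(4, 1, 6), rng.normal(8, 1, 6)])
        X = _centre(x[:, None])
        g = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        m = fit_plsda_multiclass(X, g, n_components=1)
        assert m.r2x == pytest.approx(1.0, abs=1e-9)

    def test_two_classes_rejected(self, rng):
        with pytest.raises(ValueError, match="oplsda"):
            fit_plsda_multiclass(rng.normal(size=(8, 3)), ["a"] * 4 + ["b"] * 4)


class TestVip:
    def test_informative_feature_attains_maximum(self, rng):
        X = rng.normal(size=(40, 25))
        X[:20, 7] += 5.0
        g = np.array(["a"] * 20 + ["b"] * 20)
        m = fit_oplsda(_centre(X), g, n_orthogonal=0)
        vip = compute_vip(m).vip
        assert vip.idxmax() == "x7"
        assert vip.max() > 1.0

    def test_identical_copies_all_one(self, rng):
        col = rng.normal(size=30)
        col[:15] += 3
        X = _centre(np.tile(col[:, None], (1, 6)))
        g = np.array(["a"] * 15 + ["b"] * 15)
        vip = compute_vip(fit_oplsda(X, g, n_orthogonal=0)).vip
        np.testing.assert_allclose(vip.to_numpy(), 1.0, atol=1e-9)

    @pytest.mark.parametrize("n_orth", [0, 1, 2])
    def test_mean_squared_vip_is_one(self, rng, n_orth):
        X = _centre(rng.normal(size=(30, 18)))
        X[:15, 2] += 2
        g = np.array(["a"] * 15 + ["b"] * 15)
        for basis in ("predictive_only", "all_components"):
            vip = compute_vip(fit_oplsda(X, g, n_orthogonal=n_orth), basis).vip
            assert float((vip**2).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_multiclass_mean_squared_vip_is_one(self, rng):
        X, g = TestPlsdaMulticlass._three_groups(rng)
        vip = compute_vip(fit_plsda_multiclass(X, g)).vip
        assert float((vip**2).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_no_explained_y_variance_rejected(self, rng):
        m = fit_oplsda(_centre(rng.normal(size=(20, 5))),
                       ["a"] * 10 + ["b"] * 10, n_orthogonal=0)
        m.ssy_per_component = np.array([0.0])
        with pytest.raises(ValueError):
            compute_vip(m)


class TestAutoOrthogonal:
    @staticmethod
    def _validator(n_folds=5, seed=0):
        def val(x, g, ao):
            return cross_validate_q2(
                x, g, ModelSpec("oplsda", n_orthogonal=ao), n_folds=n_folds, seed=seed
            ).q2
        return val

    @staticmethod
    def _confounded(rng):
        # confound direction with ~10x the variance of the predictive one
        n = 40
        X = rng.normal(size=(n, 30))
        X += np.outer(rng.normal(size=n) * 3.2, rng.normal(size=30))
        g = np.array(["a"] * 20 + ["b"] * 20)
        X[g == "a", 0] += 3.0
        return _centre(X), g

    def test_strong_confound_selects_orthogonal_component(self, rng):
        X, g = self._confounded(rng)
        m, trace = auto_orthogonal(X, g, self._validator())
        assert m.n_orthogonal >= 1
        assert trace[0][0] == 0

    def test_infinite_gain_returns_base_model(self, rng):
        X, g = self._confounded(rng)
        m, _ = auto_orthogonal(X, g, self._validator(), q2_gain_min=np.inf)
        assert m.n_orthogonal == 0

    def test_max_orthogonal_zero_caps_selection(self, rng):
        X, g = self._confounded(rng)
        m, trace = auto_orthogonal(X, g, self._validator(), max_orthogonal=0)
        assert m.n_orthogonal == 0 and len(trace) == 1

    def test_validator_required(self, rng):
        with pytest.raises(ValueError):
            auto_orthogonal(rng.normal(size=(10, 3)), ["a"] * 5 + ["b"] * 5, None)
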