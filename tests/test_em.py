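"""The unconditional EM core: densities, initialization, fitting."""

import math

import numpy as np
import pytest

from mixstock import (
    EMControls,
    MixtureFit,
    ObservationTable,
    em_fit,
    init_known,
    init_proportions,
    init_unknown,
    initialize,
    joint_loglik,
    mvn_logdensity,
    random_baseline,
    regularize_cov,
    seeded_kmeans,
)
from mixstock.baseline import ElementPanel
from mixstock.simulate import draw_mixed_dataset, draw_nursery_dataset


def table(x, panel=None, source=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if panel is None:
        panel = ElementPanel(tuple(f"v{j}" for j in range(x.shape[1])))
    return ObservationTable.from_arrays(x, panel, cohort="c", source=source)


class TestMvnLogdensity:
    def test_univariate_standard_normal_at_mean(self):
        assert mvn_logdensity([0.0], [0.0], [[1.0]]) == pytest.approx(
            -0.5 * math.log(2 * math.pi))

    def test_translation_invariance(self, rng):
        x, mu, shift = rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
        cov = np.diag([1.0, 2.0, 0.5])
        assert mvn_logdensity(x + shift, mu + shift, cov) == pytest.approx(
            mvn_logdensity(x, mu, cov))

    def test_bivariate_closed_form(self):
        # x - mu = (1, 2), cov = diag(1, 4):
        # -(ln 2pi + 0.5 ln 4 + 0.5 (1 + 1))
        val = mvn_logdensity([1.0, 2.0], [0.0, 0.0], np.diag([1.0, 4.0]))
        assert val == pytest.approx(-(math.log(2 * math.pi)
                                      + 0.5 * math.log(4.0) + 1.0))

    def test_matches_scipy(self, rng):
        from scipy.stats import multivariate_normal
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        x, mu = rng.normal(size=2), rng.normal(size=2)
        assert mvn_logdensity(x, mu, cov) == pytest.approx(
            multivariate_normal.logpdf(x, mu, cov))

    def test_non_pd_covariance_raises(self):
        with pytest.raises(ValueError, match="positive definite"):
            mvn_logdensity([0.0, 0.0], [0.0, 0.0], np.diag([1.0, -1.0]))


class TestJointLoglik:
    def test_brute_force_oracle_on_tiny_instance(self):
        """Three points, two components, fixed parameters: sum by hand."""
        mus = np.array([[0.0, 0.0], [3.0, 0.0]])
        covs = np.array([np.eye(2), np.diag([2.0, 1.0])])
        p = np.array([0.3, 0.7])
        lab = table([[0.1, 0.2]], source=["A"])
        mix = table([[1.0, 1.0], [2.5, -0.5]])
        got = joint_loglik(lab, mix, p, mus, covs, ["A", "B"])
        expected = mvn_logdensity([0.1, 0.2], mus[0], covs[0])
        for y in mix.values():
            expected += math.log(
                p[0] * math.exp(mvn_logdensity(y, mus[0], covs[0]))
                + p[1] * math.exp(mvn_logdensity(y, mus[1], covs[1])))
        assert got == pytest.approx(expected)

    def test_no_labeled_reduces_to_pure_mixture(self):
        mus = np.array([[0.0, 0.0], [2.0, 1.0]])
        covs = np.array([np.eye(2), np.eye(2)])
        p = np.array([0.5, 0.5])
        mix = table([[0.5, 0.1], [1.5, 0.8]])
        got = joint_loglik(None, mix, p, mus, covs, ["n1", "n2"])
        expected = sum(
            math.log(0.5 * math.exp(mvn_logdensity(y, mus[0], covs[0]))
                     + 0.5 * math.exp(mvn_logdensity(y, mus[1], covs[1])))
            for y in mix.values())
        assert got == pytest.approx(expected)

    def test_single_component_is_total_mvn_loglik(self):
        mix = table([[0.0, 0.5], [1.0, -0.5], [2.0, 0.0]])
        mu, cov = np.array([1.0, 0.0]), np.diag([2.0, 1.0])
        got = joint_loglik(None, mix, np.array([1.0]),
                           mu[None], cov[None], ["A"])
        expected = sum(mvn_logdensity(y, mu, cov) for y in mix.values())
        assert got == pytest.approx(expected)

    def test_orphan_labeled_source_raises(self):
        lab = table([[0.0, 0.0]], source=["X"])
        with pytest.raises(ValueError, match="X"):
            joint_loglik(lab, None, np.array([1.0]),
                         np.zeros((1, 2)), np.array([np.eye(2)]), ["A"])


class TestInitKnown:
    def test_per_source_sample_moments(self):
        lab = table([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]],
                    source=["A"] * 4)
        mus, covs, ids = init_known(lab)
        assert ids == ["A"]
        np.testing.assert_allclose(mus[0], [1.0, 1.0])
        np.testing.assert_allclose(covs[0],
                                   np.cov(lab.values(), rowvar=False))

    def test_empty_table_gives_empty_parameters(self):
        mus, covs, ids = init_known(None)
        assert ids == [] and mus.size == 0

    def test_degenerate_source_uses_regularized_fallback(self):
        # duplicate rows only: sample covariance is singular
        lab = table([[1.0, 1.0]] * 5, source=["A"] * 5)
        mus, covs, ids = init_known(lab)
        assert np.all(np.linalg.eigvalsh(covs[0]) > 0)

    def test_small_group_falls_back_to_pooled(self):
        rows = np.vstack([np.random.default_rng(0).normal(size=(30, 3)),
                          [[5.0, 5.0, 5.0], [5.1, 5.0, 5.0]]])
        lab = table(rows, source=["A"] * 30 + ["B"] * 2)
        mus, covs, ids = init_known(lab)
        assert np.all(np.linalg.eigvalsh(covs[ids.index("B")]) > 0)


class TestSeededKmeans:
    def test_reduces_to_ordinary_kmeans_wcss(self, rng):
        """No fixed centroids: WCSS should match scikit-learn's K-means."""
        from sklearn.cluster import KMeans
        X = np.vstack([rng.normal(0, 1, size=(40, 2)),
                       rng.normal(8, 1, size=(40, 2))])
        mobile, assign = seeded_kmeans(X, np.empty((0, 2)), 2,
                                       restarts=5, seed=0)
        sk = KMeans(n_clusters=2, n_init=5, random_state=0).fit(X)
        wcss = sum(np.sum((X[assign == u] - mobile[u]) ** 2)
                   for u in range(2))
        assert wcss == pytest.approx(sk.inertia_, rel=1e-6)

    def test_mobile_centroid_finds_uncovered_blob(self, rng):
        blob_a = rng.normal(0, 1, size=(50, 2))
        blob_b = rng.normal([10.0, 0.0], 1, size=(50, 2))
        X = np.vstack([blob_a, blob_b])
        fixed = np.array([[0.0, 0.0]])
        mobile, assign = seeded_kmeans(X, fixed, 1, restarts=5, seed=1)
        assert np.linalg.norm(mobile[0] - [10.0, 0.0]) < 1.0
        # fixed centroid keeps blob A
        assert (assign[:50] == 0).mean() > 0.9

    def test_only_mobile_centroids_move(self, rng):
        X = rng.normal(size=(30, 2))
        fixed = np.array([[5.0, 5.0]])
        mobile, assign = seeded_kmeans(X, fixed, 1, restarts=3, seed=2)
        # points nearest the far fixed centroid would be none; all mobile
        assert (assign == 1).all()
        np.testing.assert_allclose(mobile[0], X.mean(axis=0), atol=1e-8)

    def test_assignments_are_nearest_centroid(self, rng):
        X = rng.normal(size=(60, 3))
        fixed = rng.normal(size=(2, 3))
        mobile, assign = seeded_kmeans(X, fixed, 2, restarts=4, seed=3)
        cents = np.vstack([fixed, mobile])
        d2 = ((X[:, None, :] - cents[None]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(assign, d2.argmin(axis=1))

    def test_k_larger_than_n_raises(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            seeded_kmeans(rng.normal(size=(3, 2)), np.empty((0, 2)), 5)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 2))
        a = seeded_kmeans(X, np.empty((0, 2)), 3, restarts=5, seed=7)
        b = seeded_kmeans(X, np.empty((0, 2)), 3, restarts=5, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestInitUnknown:
    def test_single_cluster_gets_pooled_moments(self, rng):
        X = rng.normal(size=(40, 2))
        t = table(X)
        assign = np.zeros(40, dtype=int)
        mus, covs, tags = init_unknown(t, assign, X.mean(axis=0)[None, :], 0)
        np.testing.assert_allclose(mus[0], X.mean(axis=0))
        np.testing.assert_allclose(covs[0], np.cov(X, rowvar=False),
                                   atol=1e-6)
        assert tags == ["novel-1"]

    def test_two_clean_clusters_get_their_own_moments(self, rng):
        a = rng.normal(0, 1, size=(30, 2))
        b = rng.normal(20, 1, size=(30, 2))
        t = table(np.vstack([a, b]))
        assign = np.array([0] * 30 + [1] * 30)
        cents = np.array([a.mean(axis=0), b.mean(axis=0)])
        mus, covs, _ = init_unknown(t, assign, cents, 0)
        np.testing.assert_allclose(covs[0], np.cov(a, rowvar=False),
                                   atol=1e-6)
        np.testing.assert_allclose(covs[1], np.cov(b, rowvar=False),
                                   atol=1e-6)

    def test_empty_cluster_keeps_centroid_with_pooled_cov(self, rng):
        X = rng.normal(size=(20, 2))
        t = table(X)
        assign = np.zeros(20, dtype=int)   # cluster 1 empty
        cents = np.array([[0.0, 0.0], [9.0, 9.0]])
        mus, covs, _ = init_unknown(t, assign, cents, 0)
        np.testing.assert_array_equal(mus[1], [9.0, 9.0])
        np.testing.assert_allclose(covs[1], covs[0])


class TestInitProportions:
    def test_symmetric_data_gives_half_half(self):
        mus = np.array([[-1.0, 0.0], [1.0, 0.0]])
        covs = np.array([np.eye(2), np.eye(2)])
        mix = table([[-2.0, 0.0], [-0.5, 0.3], [0.5, 0.3], [2.0, 0.0]])
        np.testing.assert_allclose(init_proportions(mix, mus, covs),
                                   [0.5, 0.5])

    def test_enumeration_oracle_on_five_points(self):
        mus = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        covs = np.array([np.eye(2), 2 * np.eye(2), np.diag([0.5, 1.0])])
        pts = np.array([[0.1, 0.0], [3.8, 0.2], [4.2, -0.1],
                        [0.0, 3.9], [0.2, 0.1]])
        mix = table(pts)
        # brute-force densities per point
        counts = np.zeros(3)
        for y in pts:
            dens = [mvn_logdensity(y, mus[k], covs[k]) for k in range(3)]
            counts[int(np.argmax(dens))] += 1
        expected = counts / 5
        np.testing.assert_allclose(init_proportions(mix, mus, covs), expected)

    def test_empty_component_floored_and_renormalized(self):
        mus = np.array([[0.0, 0.0], [100.0, 0.0]])
        covs = np.array([np.eye(2), np.eye(2)])
        mix = table([[0.0, 0.0]] * 10)
        p = init_proportions(mix, mus, covs)
        assert p[1] == pytest.approx((1 / 20) / (1 + 1 / 20))
        assert p.sum() == pytest.approx(1.0)


class TestRegularizeCov:
    def test_well_conditioned_matrix_unchanged(self):
        C = np.array([[2.0, 0.3], [0.3, 1.0]])
        np.testing.assert_allclose(regularize_cov(C), C, atol=1e-12)

    def test_rank_deficient_matrix_repaired(self):
        C = np.outer([1.0, 2.0], [1.0, 2.0])   # rank 1
        R = regularize_cov(C)
        assert np.all(np.linalg.eigvalsh(R) >= 1e-6 * (1 - 1e-6))
        assert np.linalg.det(R) >= 1e-9 * (1 - 1e-6)

    def test_determinant_floor_via_smallest_ridge(self):
        C = np.diag([1.0, 1e-18])
        R = regularize_cov(C, eig_floor=1e-20, det_floor=1e-9)
        assert np.linalg.det(R) == pytest.approx(1e-9, rel=1e-6)
        # eigenvectors preserved (diagonal stays diagonal)
        assert abs(R[0, 1]) < 1e-15


class TestEmFit:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(2.0, 1.5, size=(40, 2))
        lab = table(x[:10], source=["A"] * 10)
        mix = table(x[10:])
        fit = em_fit(lab, mix, 1)
        np.testing.assert_allclose(fit.p_hat, [1.0])
        np.testing.assert_allclose(fit.mu_hat[0], x.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(fit.cov_hat[0],
                                   np.cov(x, rowvar=False, ddof=0), atol=1e-5)

    def test_recovers_proportions_at_high_separation(self):
        base = random_baseline(2, 4, target_sep=25.0, spread=0.5, seed=5,
                               panel=ElementPanel(("a", "b", "c", "d")))
        errs = []
        for r in range(10):
            lab = draw_nursery_dataset(base, base.source_ids, 50, seed=100 + r)
            mix, truth = draw_mixed_dataset(base, (0.3, 0.7), 400,
                                            seed=200 + r)
            fit = em_fit(lab, mix, 2, controls=EMControls(seed=r))
            p = {sid: fit.p_hat[fit.provenance.index(sid)]
                 for sid in base.source_ids}
            errs.append(max(abs(p[s] - truth.allocation[s])
                            for s in base.source_ids))
        assert np.mean(errs) < 0.05

    def test_loglik_monotone_and_simplex_every_iteration(self, base4):
        lab = draw_nursery_dataset(base4, base4.source_ids[:2], 25, seed=1)
        mix, _ = draw_mixed_dataset(base4, (0.1, 0.2, 0.3, 0.4), 100, seed=2)
        fit = em_fit(lab, mix, 4, controls=EMControls(seed=3))
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9 * (1 + np.abs(trace[:-1])))
        assert fit.p_hat.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(fit.p_hat >= 0)
        for C in fit.cov_hat:
            assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_matches_generic_gaussian_mixture_without_labels(self, rng):
        """With no labeled rows our EM is a plain GMM fit: same init, same
        optimum as scikit-learn's GaussianMixture."""
        from sklearn.mixture import GaussianMixture
        X = np.vstack([rng.normal(0, 1, size=(80, 2)),
                       rng.normal([6, 3], 1.3, size=(60, 2))])
        mix = table(X)
        ctl = EMControls(seed=0, rel_tol=1e-12, eig_floor=1e-12,
                         cov_det_floor=1e-30, max_iter=2000)
        init = initialize(None, mix, 2, ctl)
        fit = em_fit(None, mix, 2, init=init, controls=ctl)
        gm = GaussianMixture(
            n_components=2, covariance_type="full", reg_covar=0.0,
            weights_init=init.p, means_init=init.mus,
            precisions_init=np.array([np.linalg.inv(C) for C in init.covs]),
            tol=1e-12, max_iter=2000)
        gm.fit(X)
        assert fit.loglik == pytest.approx(gm.score(X) * len(X), abs=1e-6)

    def test_labeled_only_returns_sample_estimates(self, rng):
        lab = table(rng.normal(size=(30, 2)),
                    source=["A"] * 15 + ["B"] * 15)
        fit = em_fit(lab, None, 2)
        assert not fit.p_estimated
        np.testing.assert_allclose(fit.p_hat, [0.5, 0.5])
        np.testing.assert_allclose(fit.mu_hat[0],
                                   lab.values()[:15].mean(axis=0))

    def test_k_below_labeled_sources_raises(self, rng):
        lab = table(rng.normal(size=(10, 2)), source=["A"] * 5 + ["B"] * 5)
        mix = table(rng.normal(size=(10, 2)))
        with pytest.raises(ValueError, match="below"):
            initialize(lab, mix, 1)

    def test_labeled_rows_anchor_their_component(self, base4):
        """Known-source labels pin provenance: fitted means stay near the
        labeled sample means, not some permutation."""
        ids = base4.source_ids
        lab = draw_nursery_dataset(base4, ids, 25, seed=4)
        mix, _ = draw_mixed_dataset(base4, (0.1, 0.2, 0.3, 0.4), 100, seed=5)
        fit = em_fit(lab, mix, 4, controls=EMControls(seed=6))
        assert fit.provenance == ids
        for k, sid in enumerate(ids):
            d_own = np.sum((fit.mu_hat[k] - base4[sid].mu) ** 2)
            others = [np.sum((fit.mu_hat[k] - base4[o].mu) ** 2)
                      for o in ids if o != sid]
            assert d_own < min(others)

    def test_serialization_round_trip(self, tmp_path, rng):
        mix = table(rng.normal(size=(30, 2)))
        fit = em_fit(None, mix, 2, controls=EMControls(seed=1))
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = MixtureFit.from_json(path)
        assert back.K == fit.K
        np.testing.assert_array_equal(back.p_hat, fit.p_hat)
        np.testing.assert_array_equal(back.cov_hat, fit.cov_hat)
        assert back.provenance == fit.provenance
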