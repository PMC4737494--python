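"""NMDS, LDA, resampled validation and Monte-Carlo nulls."""

import numpy as np
import pytest
import scipy.linalg

from hostvar import chemclass
from hostvar.types import DistanceMatrix, HostvarError


def _line_matrix(n=6):
    x = np.arange(float(n))
    return DistanceMatrix([f"p{i}" for i in range(n)],
                          np.abs(x[:, None] - x[None, :]))


def _two_class_data(rng, n=60, p=10, sep=3.0):
    X = np.vstack([rng.normal(0, 1, (n, p)), rng.normal(sep, 1, (n, p))])
    labels = np.array(["uncolonized"] * n + ["colonized"] * n)
    return X, labels


class TestNmds:
    def test_embeddable_line_has_near_zero_stress(self):
        _, stress = chemclass.nmds(_line_matrix(), 1, n_starts=5, seed=0)
        assert stress < 0.5

    def test_scree_monotone(self, rng):
        X = rng.normal(size=(12, 6))
        from scipy.spatial.distance import pdist, squareform
        dm = DistanceMatrix(list(range(12)), squareform(pdist(X)))
        stresses = [chemclass.nmds(dm, k, n_starts=5, seed=3)[1]
                    for k in (1, 2, 3, 4)]
        assert all(stresses[i] >= stresses[i + 1] - 1e-6
                   for i in range(len(stresses) - 1))

    def test_agrees_with_independent_implementation(self, rng):
        """Stress within 1 stress unit of sklearn's nonmetric MDS on a
        fixed 6-point 2-D cloud."""
        sklearn_manifold = pytest.importorskip("sklearn.manifold")
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [2.1, 1.0],
                        [0.3, 2.0], [1.7, 2.2], [3.0, 0.5]])
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(pts))
        dm = DistanceMatrix(list("abcdef"), D)
        _, ours = chemclass.nmds(dm, 2, n_starts=10, seed=1)
        mds = sklearn_manifold.MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            n_init=10, random_state=1, normalized_stress=True, max_iter=500,
        )
        mds.fit(D)
        theirs = 100.0 * mds.stress_
        assert abs(ours - theirs) <= 1.0

    def test_dimension_bounds(self):
        with pytest.raises(HostvarError):
            chemclass.nmds(_line_matrix(4), 4)
        with pytest.raises(HostvarError):
            chemclass.nmds(_line_matrix(4), 0)


class TestLdaFit:
    def test_two_point_classes_single_axis(self, rng):
        x = np.concatenate([rng.normal(-2, 1, 30), rng.normal(2, 1, 30)])[:, None]
        labels = ["a"] * 30 + ["b"] * 30
        m = chemclass.lda_fit(x, labels)
        assert m.discriminant_axes.shape == (1, 1)
        assert np.allclose(m.proportion_of_trace, [1.0])

    def test_identical_means_no_separation(self, rng):
        X = rng.normal(size=(80, 5))
        labels = ["a"] * 40 + ["b"] * 40
        m = chemclass.lda_fit(X, labels)
        # between-class eigenvalue should be tiny relative to a separated case
        proj = m.transform(X)[:, 0]
        gap = abs(proj[:40].mean() - proj[40:].mean())
        assert gap < 1.5  # within-class SD is 1 after scaling

    def test_eigenvalues_match_dense_generalized_solve(self, rng):
        """Axis eigenvalues equal those of a brute-force solve of
        inv(S_W) S_B for a 3-class 2-D configuration."""
        means = np.array([[0, 0], [3, 0], [0, 3]])
        X = np.vstack([rng.normal(m, 1.0, size=(25, 2)) for m in means])
        labels = np.repeat(["a", "b", "c"], 25)
        m = chemclass.lda_fit(X, labels)
        # independent brute-force scatter computation
        mu = X.mean(axis=0)
        S_W = np.zeros((2, 2))
        S_B = np.zeros((2, 2))
        for lab in "abc":
            sub = X[labels == lab]
            d = sub - sub.mean(axis=0)
            S_W += d.T @ d
            dm = (sub.mean(axis=0) - mu)[:, None]
            S_B += len(sub) * dm @ dm.T
        brute = np.sort(np.real(np.linalg.eigvals(np.linalg.inv(S_W) @ S_B)))[::-1]
        assert np.allclose(m.proportion_of_trace, brute / brute.sum(), atol=1e-8)

    def test_proportion_of_trace_properties(self, rng):
        X = rng.normal(size=(90, 6))
        X[:30] += 2
        X[30:60] += np.array([0, 1, 0, 0, 0, 0.5])
        labels = np.repeat(["a", "b", "c"], 30)
        m = chemclass.lda_fit(X, labels)
        assert m.proportion_of_trace.sum() == pytest.approx(1.0)
        assert all(np.diff(m.proportion_of_trace) <= 1e-12)
        assert m.discriminant_axes.shape[1] == 2  # min(classes-1, features)

    def test_singular_within_scatter_gets_ridge(self, rng):
        X = rng.normal(size=(10, 20))  # more features than samples
        labels = ["a"] * 5 + ["b"] * 5
        with pytest.warns(UserWarning, match="ridge"):
            m = chemclass.lda_fit(X, labels)
        assert m.ridge_used > 0

    def test_small_class_error_names_class(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(HostvarError, match="'b'"):
            chemclass.lda_fit(X, ["a", "a", "a", "a", "b"])

    def test_affine_invariance_of_accuracy(self, rng):
        X, labels = _two_class_data(rng, n=40, sep=1.0)
        r1 = chemclass.resampled_validation(X, labels, 50, 25, 50, seed=9)
        r2 = chemclass.resampled_validation(X * 3.7 + 11.0, labels, 50, 25, 50,
                                            seed=9)
        assert np.allclose(r1.accuracy_per_iteration, r2.accuracy_per_iteration,
                           atol=1e-9)


class TestResampledValidation:
    def test_separable_scenario_high_accuracy(self, rng):
        X, labels = _two_class_data(rng, sep=4.0)
        res = chemclass.resampled_validation(X, labels, 80, 40, 200, seed=1)
        assert res.mean_accuracy > 0.95
        assert res.ci95[0] <= res.mean_accuracy <= res.ci95[1]

    def test_uninformative_features_hit_base_rate(self, rng):
        """With features independent of status, accuracy ~ majority-class
        fraction within 3 SE over iterations."""
        n0, n1 = 70, 50
        X = rng.normal(size=(n0 + n1, 8))
        labels = np.array(["u"] * n0 + ["c"] * n1)
        res = chemclass.resampled_validation(X, labels, 80, 40, 400, seed=2)
        base = n0 / (n0 + n1)
        se = res.accuracy_per_iteration.std(ddof=1) / np.sqrt(400)
        # the classifier uses equal priors, so chance sits between 0.5 and
        # the base rate; allow the wider of the two bands
        assert 0.5 - 5 * se <= res.mean_accuracy <= base + 5 * se

    def test_single_iteration_reproducible(self, rng):
        X, labels = _two_class_data(rng, n=30)
        a = chemclass.resampled_validation(X, labels, 30, 15, 1, seed=5)
        b = chemclass.resampled_validation(X, labels, 30, 15, 1, seed=5)
        assert a.accuracy_per_iteration[0] == b.accuracy_per_iteration[0]

    def test_impossible_split_errors(self, rng):
        X, labels = _two_class_data(rng, n=10)
        with pytest.raises(HostvarError):
            chemclass.resampled_validation(X, labels, 18, 5, 10)


class TestNullValidation:
    def test_minimum_p_on_separable_data(self, rng):
        X, labels = _two_class_data(rng, n=40, sep=5.0)
        obs, null, p = chemclass.null_validation(
            X, labels, "permute_plants", n_perm=199, inner_iter=10,
            n_train=50, n_valid=25, seed=3,
        )
        assert p == pytest.approx(1.0 / 200.0)
        assert obs > 0.95

    def test_label_permutation_null_centers_on_chance(self, rng):
        X, labels = _two_class_data(rng, n=40, sep=5.0)
        _, null, _ = chemclass.null_validation(
            X, labels, "permute_plants", n_perm=60, inner_iter=30,
            n_train=50, n_valid=25, seed=4,
        )
        se = null.std(ddof=1) / np.sqrt(len(null))
        assert abs(null.mean() - 0.5) < max(3 * se, 0.05)

    def test_covariance_null_destroys_correlation_signal(self, rng):
        """When the class signal lives only in the covariance of a compound
        pair, shuffling within compounds drives accuracy toward chance."""
        n = 60
        z = rng.normal(size=n, scale=2.0)  # shared latent: compounds correlate
        d = 0.8
        shift = np.where(np.arange(n) < n // 2, -d, d)
        x1 = z + 0.2 * rng.normal(size=n)
        x2 = z + shift + 0.2 * rng.normal(size=n)  # x2 - x1 carries the class
        X = np.column_stack([x1, x2])
        labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        obs, null, p = chemclass.null_validation(
            X, labels, "permute_within_compound", n_perm=40, inner_iter=40,
            n_train=40, n_valid=20, seed=6,
        )
        assert obs > 0.8          # covariance signal is learnable
        assert null.mean() < 0.65  # and dies under within-compound shuffling
        assert p <= 0.05

    def test_bad_null_type(self, rng):
        X, labels = _two_class_data(rng, n=10)
        with pytest.raises(HostvarError):
            chemclass.null_validation(X, labels, "bogus", 5, 5)


class TestScoresVsPerformance:
    def _model_and_data(self, rng):
        pops = np.repeat([f"P{i}" for i in range(5)], 12)
        X = rng.normal(size=(60, 3)) + np.repeat(
            np.arange(5)[:, None] * [1.0, 0.0, 0.0], 12, axis=0)
        model = chemclass.lda_fit(X, pops)
        return model, X, pops

    def test_monotone_performance_gives_rho_one(self, rng):
        model, X, pops = self._model_and_data(rng)
        Z = model.transform(X)[:, 0]
        means = {p: Z[pops == p].mean() for p in sorted(set(pops))}
        perf = {p: 2.0 * v + 1.0 for p, v in means.items()}
        res = chemclass.discriminant_scores_vs_performance(model, X, pops, perf)
        assert res[0][0] == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self, rng):
        model, X, pops = self._model_and_data(rng)
        Z = model.transform(X)[:, 0]
        means = {p: Z[pops == p].mean() for p in sorted(set(pops))}
        perf = {p: -v for p, v in means.items()}
        res = chemclass.discriminant_scores_vs_performance(model, X, pops, perf)
        assert res[0][0] == pytest.approx(-1.0)

    def test_too_few_populations(self, rng):
        model, X, pops = self._model_and_data(rng)
        with pytest.raises(HostvarError):
            chemclass.discriminant_scores_vs_performance(
                model, X, pops, {"P0": 1, "P1": 2, "P2": 3})
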