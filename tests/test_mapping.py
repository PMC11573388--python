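"""State-to-synergy mapping: labeling, naive Bayes posteriors, surfaces, PCA."""

import numpy as np
import pytest
from scipy.stats import norm

from stsmap import mapping as mp


def bayes_oracle(priors, means, variances, point):
    """Independent brute-force Bayes posterior for a 2-feature Gaussian model."""
    joint = []
    for c in range(len(priors)):
        lik = 1.0
        for f in range(2):
            lik *= norm.pdf(point[f], means[c][f], np.sqrt(variances[c][f]))
        joint.append(priors[c] * lik)
    joint = np.array(joint)
    return joint / joint.sum()


class TestLabelMostActive:
    def test_basic_argmax(self):
        np.testing.assert_array_equal(
            mp.label_most_active(np.array([[1.0, 0.0], [0.0, 1.0]])), [0, 1]
        )

    def test_single_synergy(self):
        np.testing.assert_array_equal(mp.label_most_active(np.array([[2.0, 2.0]])), [0, 0])

    def test_row_rescaling_changes_argmax(self):
        # row 1 dominates raw amplitude everywhere, but each row wins at its own peak
        H = np.array([[1.0, 0.8], [2.0, 10.0]])
        np.testing.assert_array_equal(mp.label_most_active(H), [0, 1])
        np.testing.assert_array_equal(mp.label_most_active(H, rescale=False), [1, 1])

    def test_zero_column_carries_previous_label_forward(self):
        H = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
        np.testing.assert_array_equal(mp.label_most_active(H), [0, 0, 0])
        H2 = np.array([[0.0, 0.0], [1.0, 0.0]])
        np.testing.assert_array_equal(mp.label_most_active(H2), [1, 1])

    def test_transition_at_analytic_gaussian_crossing(self):
        # equal-width, equal-height bumps cross exactly midway between centers
        t = np.linspace(0.0, 1.0, 200)
        c1, c2, w = 0.3, 0.7, 0.12
        H = np.vstack([
            np.exp(-0.5 * ((t - c1) / w) ** 2),
            np.exp(-0.5 * ((t - c2) / w) ** 2),
        ])
        labels = mp.label_most_active(H)
        crossing = np.flatnonzero(np.diff(labels))[0] + 1
        expected = np.argmin(np.abs(t - (c1 + c2) / 2))
        assert abs(crossing - expected) <= 2


class TestFeaturePairs:
    def test_pairs_select_named_columns(self, rng):
        series = {name: rng.normal(size=30) for name in mp.VARIABLE_NAMES}
        pairs = mp.make_feature_pairs(series)
        assert set(pairs) == set(mp.FEATURE_PAIRS)
        np.testing.assert_array_equal(
            pairs["cartesian position-position"],
            np.column_stack([series["x"], series["y"]]),
        )
        np.testing.assert_array_equal(
            pairs["cartesian AP position-velocity"],
            np.column_stack([series["x"], series["vx"]]),
        )
        np.testing.assert_array_equal(
            pairs["polar position-position"],
            np.column_stack([series["mag"], series["ang"]]),
        )


class TestGaussianNaiveBayes:
    def test_symmetric_two_class_boundary(self, rng):
        X = np.vstack([
            rng.normal(0.0, 1.0, size=(500, 2)),
            rng.normal(10.0, 1.0, size=(500, 2)),
        ])
        y = np.repeat([0, 1], 500)
        smap = mp.fit_gnb(X, y)
        # force exactly symmetric parameters, then probe the midpoint
        smap.means = np.array([[0.0, 0.0], [10.0, 10.0]])
        smap.variances = np.ones((2, 2))
        smap.class_priors = np.array([0.5, 0.5])
        proba = mp.predict_proba(smap, np.array([5.0, 5.0]))
        np.testing.assert_allclose(proba, [0.5, 0.5], atol=1e-9)

    def test_single_class_is_certain(self, rng):
        X = rng.normal(size=(20, 2))
        smap = mp.fit_gnb(X, np.zeros(20, dtype=int))
        assert mp.predict_proba(smap, np.array([3.0, -3.0]))[0] == pytest.approx(1.0)

    def test_three_class_hand_oracle(self):
        priors = [0.5, 0.3, 0.2]
        means = [[0.0, 0.0], [2.0, -1.0], [-1.0, 3.0]]
        variances = [[1.0, 2.0], [0.5, 1.0], [2.0, 0.3]]
        smap = mp.SynergyMap(
            classes=np.array([0, 1, 2]),
            class_priors=np.array(priors),
            means=np.array(means),
            variances=np.array(variances),
        )
        point = np.array([0.7, 0.4])
        np.testing.assert_allclose(
            mp.predict_proba(smap, point),
            bayes_oracle(priors, means, variances, point),
            atol=1e-10,
        )

    def test_posterior_fuzz_against_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            priors = rng.dirichlet(np.ones(3))
            means = rng.normal(0, 3, size=(3, 2))
            variances = rng.uniform(0.1, 4.0, size=(3, 2))
            smap = mp.SynergyMap(
                classes=np.arange(3), class_priors=priors,
                means=means, variances=variances,
            )
            point = rng.normal(0, 3, size=2)
            np.testing.assert_allclose(
                mp.predict_proba(smap, point),
                bayes_oracle(priors, means, variances, point),
                atol=1e-10,
            )

    def test_matches_sklearn_reference(self, rng):
        from sklearn.naive_bayes import GaussianNB

        X = rng.normal(0, 2, size=(300, 2)) + rng.integers(0, 3, 300)[:, None] * 3.0
        y = np.tile([0, 1, 2], 100)
        X += y[:, None] * 2.0
        smap = mp.fit_gnb(X, y)
        ref = GaussianNB().fit(X, y)
        probe = rng.normal(0, 3, size=(20, 2))
        np.testing.assert_allclose(
            mp.predict_proba(smap, probe), ref.predict_proba(probe), atol=1e-6
        )

    def test_thin_class_fails_with_class_named(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        y = np.array([0, 0, 0, 0, 7])
        with pytest.raises(ValueError, match="7"):
            mp.fit_gnb(X, y)


class TestEvaluateMapping:
    def test_separated_clusters_perfect_accuracy(self, rng):
        X = np.vstack([
            rng.normal(0, 0.1, size=(200, 2)),
            rng.normal(5, 0.1, size=(200, 2)),
            rng.normal([0, 9], 0.1, size=(200, 2)),
        ])
        y = np.repeat([0, 1, 2], 200)
        assert mp.evaluate_mapping(X, y, seed=0) == 1.0

    def test_shuffled_labels_at_chance(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(3000, 2))
            y = np.tile([0, 1, 2], 1000)
            acc = mp.evaluate_mapping(X, rng.permutation(y), seed=seed)
            assert 0.28 <= acc <= 0.39


class TestProbabilitySurface:
    def _toy_map(self):
        return mp.SynergyMap(
            classes=np.array([0, 1]),
            class_priors=np.array([0.5, 0.5]),
            means=np.array([[0.0, 0.0], [2.0, 2.0]]),
            variances=np.ones((2, 2)),
        )

    def test_node_probabilities_sum_to_one(self):
        surf = mp.probability_surface(self._toy_map(), ranges=((-1, 3), (-1, 3)), n=25)
        np.testing.assert_allclose(surf.probabilities.sum(axis=2), 1.0, atol=1e-9)

    def test_single_class_constant_surface(self, rng):
        smap = mp.fit_gnb(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))
        surf = mp.probability_surface(smap, ranges=((-2, 2), (-2, 2)), n=10)
        np.testing.assert_allclose(surf.probabilities, 1.0)

    def test_dominance_partitions_grid(self):
        surf = mp.probability_surface(self._toy_map(), ranges=((-1, 3), (-1, 3)), n=30)
        dom = surf.dominance()
        assert set(np.unique(dom)) <= {0, 1}

    def test_symmetric_boundary_is_perpendicular_bisector(self):
        # equal priors/variances: boundary is the line x + y = 2
        surf = mp.probability_surface(self._toy_map(), ranges=((-1, 3), (-1, 3)), n=101)
        dom = surf.dominance()
        XX, YY = np.meshgrid(surf.grid_x, surf.grid_y)
        step = surf.grid_x[1] - surf.grid_x[0]
        assert np.all(dom[(XX + YY) < 2 - step] == 0)
        assert np.all(dom[(XX + YY) > 2 + step] == 1)


class TestPca2d:
    def test_planar_data_fully_explained(self, rng):
        basis = rng.normal(size=(2, 8))
        coords = rng.normal(size=(300, 2))
        res = mp.pca_2d(coords @ basis)
        assert res.explained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_explains_quarter(self):
        data = np.random.default_rng(42).normal(size=(10000, 8))
        res = mp.pca_2d(data)
        assert res.explained_fraction == pytest.approx(0.25, abs=0.02)

    def test_components_orthonormal(self, rng):
        res = mp.pca_2d(rng.normal(size=(200, 8)))
        np.testing.assert_allclose(res.components.T @ res.components, np.eye(2), atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        data = rng.normal(size=(100, 8))
        a, b = mp.pca_2d(data), mp.pca_2d(data.copy())
        np.testing.assert_array_equal(a.components, b.components)
        for j in range(2):
            assert a.components[np.argmax(np.abs(a.components[:, j])), j] > 0

    def test_too_few_samples_fail(self):
        with pytest.raises(ValueError):
            mp.pca_2d(np.ones((2, 8)))


class TestRunGroupMappings:
    def _records(self, rng, n_cycles=3, n=80):
        records = []
        for _ in range(n_cycles):
            u = np.linspace(0, 1, n)
            series = {
                "x": 0.1 * np.sin(np.pi * u) + 0.01 * rng.normal(size=n),
                "y": 0.6 + 0.3 * u + 0.01 * rng.normal(size=n),
            }
            series["vx"] = np.gradient(series["x"])
            series["vy"] = np.gradient(series["y"])
            series["mag"] = np.hypot(series["x"], series["y"])
            series["ang"] = np.arctan2(series["x"], series["y"])
            series["vmag"] = np.gradient(series["mag"])
            series["vang"] = np.gradient(series["ang"])
            labels = np.digitize(u, [0.33, 0.66])
            records.append({"features": series, "labels": labels})
        return records

    def test_nine_spaces_with_valid_accuracies(self, rng):
        res = mp.run_group_mappings(self._records(rng), n_syn_group=3, seed=0)
        assert set(res.by_space) == set(mp.FEATURE_PAIRS) | {mp.PCA_SPACE}
        for r in res.by_space.values():
            assert 0.0 <= r.accuracy <= 1.0
        assert res.by_space["cartesian VT position-velocity"].accuracy > 1 / 3

    def test_deterministic_under_fixed_seed(self, rng):
        recs = self._records(rng)
        a = mp.run_group_mappings(recs, 3, seed=4)
        b = mp.run_group_mappings(recs, 3, seed=4)
        assert a.accuracy_table() == b.accuracy_table()

    def test_empty_group_fails(self):
        with pytest.raises(ValueError):
            mp.run_group_mappings([], 3)
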