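"""Adjacent-ISI GMM clustering and ensemble probabilistic distance."""

import numpy as np
import pytest

from neurostab import (
    AdjacentISIData,
    SpikeTrain,
    adjacent_isi,
    fit_gmm,
    probabilistic_distance,
    PatternDistance,
)
from neurostab._utils import child_seed
from neurostab.patterns import linkage_to_newick


class TestAdjacentISI:
    def test_pairs_from_isis(self):
        # ISI series [1, 2, 3] -> consecutive pairs (1,2) and (2,3)
        train = SpikeTrain(times=np.cumsum([0.5, 1.0, 2.0, 3.0]))
        data = adjacent_isi([train])
        np.testing.assert_allclose(data.points, [[1.0, 2.0], [2.0, 3.0]])

    def test_regular_train_single_point(self):
        train = SpikeTrain(times=np.arange(1, 50) * 0.2)
        data = adjacent_isi([train])
        assert np.allclose(data.points, data.points[0])

    def test_alternating_two_blobs(self):
        isis = np.tile([0.05, 0.5], 100)
        data = adjacent_isi([isis])
        short_long = data.points[(data.points[:, 0] < 0.1) & (data.points[:, 1] > 0.1)]
        long_short = data.points[(data.points[:, 0] > 0.1) & (data.points[:, 1] < 0.1)]
        assert short_long.shape[0] + long_short.shape[0] == data.points.shape[0]
        assert short_long.size and long_short.size  # both off-diagonal blobs

    def test_short_train_skipped_with_warning(self):
        good = SpikeTrain(times=np.cumsum(np.full(10, 0.1)))
        bad = SpikeTrain(times=np.array([0.0, 0.1]))
        with pytest.warns(UserWarning, match="skipped"):
            data = adjacent_isi([good, bad])
        assert set(np.unique(data.train_ids)) == {0}


class TestGMM:
    def test_balanced_separated_blobs(self, rng):
        pts = np.vstack(
            [rng.normal([0, 0], 0.1, (2500, 2)), rng.normal([3, 3], 0.1, (2500, 2))]
        )
        data = AdjacentISIData(points=pts, train_ids=np.zeros(5000))
        res = fit_gmm(data, 2, seed=0)
        np.testing.assert_allclose(np.sort(res.weights), [0.5, 0.5], atol=0.02)
        hard = np.argmax(res.responsibilities, axis=1)
        # >= 99% of points assigned to the component owning their blob
        m1 = np.bincount(hard[:2500]).argmax()
        m2 = np.bincount(hard[2500:]).argmax()
        assert m1 != m2
        assert np.mean(hard[:2500] == m1) >= 0.99
        assert np.mean(hard[2500:] == m2) >= 0.99

    def test_single_component(self, rng):
        pts = rng.normal(0, 1, (500, 2))
        data = AdjacentISIData(points=pts, train_ids=np.zeros(500))
        res = fit_gmm(data, 1, seed=0)
        assert res.weights[0] == pytest.approx(1.0)
        np.testing.assert_allclose(res.means[0], pts.mean(axis=0), atol=1e-6)

    def test_unbalanced_mixing_recovery(self, rng):
        pts = np.vstack(
            [rng.normal([0, 0], 0.2, (4000, 2)), rng.normal([4, 4], 0.2, (1000, 2))]
        )
        data = AdjacentISIData(points=pts, train_ids=np.zeros(5000))
        res = fit_gmm(data, 2, seed=1)
        np.testing.assert_allclose(np.sort(res.weights), [0.2, 0.8], atol=0.03)

    def test_weights_sum_to_one_and_ic_table(self, rng):
        pts = rng.normal(0, 1, (400, 2))
        res = fit_gmm(AdjacentISIData(pts, np.zeros(400)), 3, seed=2)
        assert res.weights.sum() == pytest.approx(1.0)
        assert np.allclose(res.responsibilities.sum(axis=1), 1.0)
        assert set(res.ic_table.columns) == {"k", "aic", "bic"}

    def test_too_few_points(self, rng):
        pts = rng.normal(0, 1, (15, 2))
        with pytest.raises(ValueError, match="10 points per"):
            fit_gmm(AdjacentISIData(pts, np.zeros(15)), 2, seed=0)


class TestProbabilisticDistance:
    def test_exchangeable_groups_near_zero(self):
        dists = []
        for s in range(5):
            r = np.random.default_rng(child_seed(50, s))
            groups = {
                "a": [r.gamma(1.0, 0.2, 2100)],
                "b": [r.gamma(1.0, 0.2, 2100)],
            }
            res = probabilistic_distance(groups, n_trees=300, seed=child_seed(51, s))
            dists.append(res.distances[0, 1])
        assert np.mean(dists) <= 0.10

    def test_disjoint_supports_near_one(self, rng):
        groups = {
            "fast": [rng.uniform(0.05, 0.1, 1500)],
            "slow": [rng.uniform(0.5, 1.0, 1500)],
        }
        res = probabilistic_distance(groups, n_trees=300, seed=0)
        assert res.distances[0, 1] >= 0.95

    def test_triplet_dendrogram_topology(self, rng):
        # A and B drawn from one process, C from a disjoint one
        groups = {
            "A": [rng.uniform(0.05, 0.1, 1500)],
            "B": [rng.uniform(0.05, 0.1, 1500)],
            "C": [rng.uniform(0.5, 1.0, 1500)],
        }
        res = probabilistic_distance(groups, n_trees=300, seed=1)
        i, j = int(res.linkage[0, 0]), int(res.linkage[0, 1])
        assert {res.labels[i], res.labels[j]} == {"A", "B"}

    def test_matrix_invariants(self, rng):
        groups = {
            "x": [rng.gamma(2.0, 0.1, 1200)],
            "y": [rng.gamma(1.0, 0.2, 1200)],
            "z": [rng.gamma(4.0, 0.05, 1200)],
        }
        res = probabilistic_distance(groups, n_trees=100, seed=2)
        D = res.distances
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0)
        assert np.all((D >= 0) & (D <= 1))

    def test_monotone_in_separation(self):
        # distance never decreases as the mean-ISI separation grows
        shifts = [0.0, 0.05, 0.1, 0.2, 0.4]
        means = []
        for shift in shifts:
            d = []
            for s in range(10):
                r = np.random.default_rng(child_seed(60, s))
                groups = {
                    "a": [r.gamma(4.0, 0.05, 1300)],
                    "b": [r.gamma(4.0, 0.05, 1300) + shift],
                }
                d.append(
                    probabilistic_distance(
                        groups, n_trees=100, seed=child_seed(61, s)
                    ).distances[0, 1]
                )
            means.append(np.mean(d))
        diffs = np.diff(means)
        assert np.all(diffs >= -0.02)

    def test_small_group_rejected(self, rng):
        groups = {"a": [rng.gamma(1.0, 0.2, 100)], "b": [rng.gamma(1.0, 0.2, 2000)]}
        with pytest.raises(ValueError, match="'a'"):
            probabilistic_distance(groups)


class TestNewick:
    def test_newick_parses_with_skbio(self, rng):
        import io as _io

        import skbio

        groups = {
            "A": [rng.uniform(0.05, 0.1, 1200)],
            "B": [rng.uniform(0.05, 0.1, 1200)],
            "C": [rng.uniform(0.5, 1.0, 1200)],
        }
        res = probabilistic_distance(groups, n_trees=100, seed=3)
        tree = skbio.TreeNode.read(_io.StringIO(res.newick))
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}
        # A and B are siblings in the parsed tree
        tip_a = [t for t in tree.tips() if t.name == "A"][0]
        sibling_names = {t.name for t in tip_a.parent.children if t.name}
        assert sibling_names == {"A", "B"}

    def test_linkage_to_newick_two_leaves(self):
        Z = np.array([[0.0, 1.0, 0.8, 2.0]])
        nwk = linkage_to_newick(Z, ["x", "y"])
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "x:" in nwk and "y:" in nwk


def test_estimator_api(rng):
    groups = {
        "a": [rng.uniform(0.05, 0.1, 1300)],
        "b": [rng.uniform(0.5, 1.0, 1300)],
    }
    est = PatternDistance(n_trees=100, seed=0).fit(groups)
    assert est.distances_[0, 1] > 0.9
    assert est.labels_ == ["a", "b"]
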