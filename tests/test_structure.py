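import itertools

import numpy as np
import pytest

from popfound import nj_tree, p_distance, pca
from popfound.structure import DistanceMatrix

from conftest import bn_pair, make_matrix, random_matrix


class TestPCA:
    def test_two_samples_put_all_variance_on_pc1(self):
        g = make_matrix([[0, 1, 2, 0], [2, 1, 0, 2]])
        res = pca(g, scaling="center_only")
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_duplicated_sample_has_identical_coordinates(self, rng):
        d = rng.integers(0, 3, size=(6, 100))
        d[5] = d[0]
        res = pca(make_matrix(d))
        assert np.allclose(res.coordinates[0], res.coordinates[5])

    def test_sample_order_permutation_invariance(self, rng):
        g = random_matrix(rng, n_samples=10, n_sites=120, missing_rate=0.05)
        perm = rng.permutation(10)
        res1 = pca(g)
        res2 = pca(g.take_samples(perm))
        # eigen-scores match up to sign after undoing the permutation
        for k in range(3):
            a, b = res1.coordinates[perm, k], res2.coordinates[:, k]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
        assert np.allclose(res1.variance_explained, res2.variance_explained)

    def test_variance_fractions_monotone_and_bounded(self, rng):
        g = random_matrix(rng, n_samples=12, n_sites=200, missing_rate=0.1)
        res = pca(g)
        v = res.variance_explained
        assert (np.diff(v) <= 1e-12).all()
        assert v.sum() <= 1.0 + 1e-9

    def test_two_populations_separate_on_pc1(self):
        g, pops = bn_pair(0.1, 40, 2000, seed=17)
        res = pca(g)
        a = res.coordinates[:40, 0]
        b = res.coordinates[40:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or (
            a.max() < b.min() or b.max() < a.min()
        )

    def test_all_monomorphic_errors(self):
        g = make_matrix(np.ones((4, 5)) * 2)
        with pytest.raises(ValueError):
            pca(g)


class TestPDistance:
    def test_definition_toys(self):
        g = make_matrix([[0], [1]])
        assert p_distance(g).d[0, 1] == pytest.approx(0.5)
        g2 = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert p_distance(g2).d[0, 1] == pytest.approx(1.0)
        g3 = make_matrix([[1, 2, 0], [1, 2, 0]])
        assert p_distance(g3).d[0, 1] == 0.0

    def test_missing_data_uses_shared_sites_only(self):
        g = make_matrix([[0, -1, 2], [2, 1, -1]])
        # only site 0 is shared: |0-2| / (2*1) = 1
        assert p_distance(g).d[0, 1] == pytest.approx(1.0)

    def test_semimetric_properties(self, rng):
        g = random_matrix(rng, n_samples=8, n_sites=60, missing_rate=0.0)
        dm = p_distance(g)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0.0)
        for i, j, k in itertools.permutations(range(8), 3):
            assert dm.d[i, j] <= dm.d[i, k] + dm.d[k, j] + 1e-12


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree, _ = nj_tree(DistanceMatrix(["x", "y", "z"], d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["x"] == pytest.approx(1.0)
        assert lengths["y"] == pytest.approx(1.0)
        assert lengths["z"] == pytest.approx(2.0)

    def test_hand_built_additive_four_taxon_tree(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree, newick = nj_tree(DistanceMatrix(list("ABCD"), d))
        tt = tree.tip_tip_distances()
        ids = list(map(str, tt.ids))
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert tt[ids.index(a), ids.index(b)] == pytest.approx(d[i, j])
        # cherry (A,B) with internal branch 1 and leaf branches 1 and 2
        ab_parent = tree.find("A").parent
        assert {t.name for t in ab_parent.tips()} == {"A", "B"}
        assert ab_parent.length == pytest.approx(1.0)
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("B").length == pytest.approx(2.0)

    @staticmethod
    def _random_additive_matrix(rng, n_taxa=8):
        """Path-length matrix of a random binary tree with positive branches."""
        from skbio.tree import TreeNode

        nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
        while len(nodes) > 3:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[j], nodes[i]  # pop higher index first
            for child in (a, b):
                child.length = float(rng.uniform(0.5, 2.0))
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
            nodes.append(TreeNode(children=[a, b]))
        for child in nodes:
            child.length = float(rng.uniform(0.5, 2.0))
        truth = TreeNode(children=nodes)
        tt = truth.tip_tip_distances()
        ids = list(map(str, tt.ids))
        labels = [f"t{i}" for i in range(n_taxa)]
        order = [ids.index(l) for l in labels]
        return labels, tt.data[np.ix_(order, order)]

    def test_additive_input_is_reproduced_exactly(self, rng):
        """On an additive matrix NJ recovers the generating tree's path lengths,
        and agrees with the independent scikit-bio implementation."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        labels, d = self._random_additive_matrix(rng)
        tree, _ = nj_tree(DistanceMatrix(labels, d))
        ours = tree.tip_tip_distances()
        ref = skbio_nj(SkbioDM(d, ids=labels)).tip_tip_distances()
        ids_a = list(map(str, ours.ids))
        ids_b = list(map(str, ref.ids))
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            assert ours[ids_a.index(a), ids_a.index(b)] == pytest.approx(d[i, j], abs=1e-9)
            assert ref[ids_b.index(a), ids_b.index(b)] == pytest.approx(d[i, j], abs=1e-9)

    def test_rejects_asymmetric_and_null_inputs(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))
        d = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], d))

    def test_newick_contains_all_labels(self, rng):
        g = random_matrix(rng, n_samples=6, n_sites=50, missing_rate=0.0)
        _, newick = nj_tree(p_distance(g))
        for s in g.sample_ids:
            assert s in newick
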