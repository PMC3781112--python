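import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aflpop.io import BinaryMarkerMatrix
from aflpop.trees import (
    BootstrapSet,
    DistanceMatrix,
    TreeNode,
    binary_distance,
    bootstrap_support,
    homoplasy_excess_scan,
    leaf_stability,
    lineage_movement,
    nj_tree,
    tree_bipartitions,
    tree_path_lengths,
)


def _matrix(data, species=None):
    data = np.asarray(data)
    n, m = data.shape
    return BinaryMarkerMatrix(
        data,
        [f"t{i}" for i in range(n)],
        [f"L{j}" for j in range(m)],
        species or ["sp"] * n,
    )


class TestBinaryDistance:
    def test_identical_rows_zero_distance(self):
        m = _matrix([[1, 0, 1], [1, 0, 1], [0, 1, 1]])
        for method in ("jaccard", "link", "p_distance"):
            d = binary_distance(m, method)
            assert d.data[0, 1] == 0.0

    def test_hand_counts(self):
        m = _matrix([[1, 1, 0], [0, 1, 1]])
        assert binary_distance(m, "jaccard").data[0, 1] == pytest.approx(1 - 1 / 3)
        assert binary_distance(m, "link").data[0, 1] == pytest.approx(0.5)
        assert binary_distance(m, "p_distance").data[0, 1] == pytest.approx(2 / 3)

    def test_disjoint_bands_maximal_jaccard(self):
        m = _matrix([[1, 0, 0], [0, 1, 0]])
        assert binary_distance(m, "jaccard").data[0, 1] == 1.0

    def test_all_absent_pair_is_error(self):
        m = _matrix([[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="shares no present band"):
            binary_distance(m, "jaccard")

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**30))
    def test_link_never_exceeds_jaccard(self, seed):
        # 2a/(2a+b+c) >= a/(a+b+c) implies d_link <= d_jaccard pairwise
        rng = np.random.default_rng(seed)
        data = (rng.random((5, 30)) < rng.uniform(0.2, 0.8)).astype(int)
        data[:, 0] = 1  # avoid undefined pairs
        m = _matrix(data)
        dj = binary_distance(m, "jaccard").data
        dl = binary_distance(m, "link").data
        assert (dl <= dj + 1e-12).all()


class TestNJ:
    def test_additive_matrix_recovered_exactly(self):
        D = np.array(
            [[0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        t = nj_tree(DistanceMatrix(["A", "B", "C", "D"], D))
        pl = tree_path_lengths(t).loc[["A", "B", "C", "D"], ["A", "B", "C", "D"]]
        np.testing.assert_allclose(pl.to_numpy(), D, atol=1e-12)
        assert tree_bipartitions(t) == {frozenset({"C", "D"})}

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(["A", "B", "C"], D))
        pl = tree_path_lengths(t).loc[["A", "B", "C"], ["A", "B", "C"]]
        np.testing.assert_allclose(pl.to_numpy(), D, atol=1e-12)

    def test_matches_skbio_topology_on_random_matrices(self):
        import skbio

        rng = np.random.default_rng(12)
        for _ in range(5):
            n = 7
            pts = rng.random((n, 4))
            D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            ids = [f"t{i}" for i in range(n)]
            mine = tree_bipartitions(nj_tree(DistanceMatrix(ids, D)))
            sk = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
            theirs = set()
            taxa = frozenset(ids)
            ref = min(taxa)
            for node in sk.non_tips():
                below = frozenset(t.name for t in node.tips())
                if 2 <= len(below) <= n - 2:
                    theirs.add(taxa - below if ref in below else below)
            assert mine == theirs

    def test_ultrametric_matrix_matches_upgma_topology(self):
        from scipy.cluster.hierarchy import average, cophenet, fcluster
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(7)
        pts = rng.random((7, 3))
        Z = average(pdist(pts))
        D = squareform(cophenet(Z))  # exactly ultrametric
        ids = [f"t{i}" for i in range(7)]
        nj_bips = tree_bipartitions(nj_tree(DistanceMatrix(ids, D)))
        # UPGMA clusters from the linkage define the clade system
        upgma_bips = set()
        taxa = frozenset(ids)
        ref = min(taxa)
        n = len(ids)
        members = {i: {ids[i]} for i in range(n)}
        for k, (a, b, _h, _c) in enumerate(Z):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            if 2 <= len(merged) <= n - 2:
                side = frozenset(merged)
                upgma_bips.add(taxa - side if ref in side else side)
        assert nj_bips == upgma_bips

    def test_nonsymmetric_rejected(self):
        bad = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], bad)

    def test_branch_lengths_never_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            D = rng.random((6, 6))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            t = nj_tree(DistanceMatrix([f"t{i}" for i in range(6)], D))

            def walk(node):
                for c in node.children:
                    assert c.length >= 0
                    walk(c)

            walk(t)


class TestBootstrap:
    def test_fixed_differences_give_full_support(self):
        data = np.zeros((8, 60), dtype=int)
        data[:4, :30] = 1
        data[4:, 30:] = 1
        m = _matrix(data)
        res = bootstrap_support(m, 80, "link", seed=1)
        clade = frozenset(f"t{i}" for i in range(4, 8))
        assert res.supports[clade] == 100.0

    def test_same_seed_identical_supports(self):
        rng = np.random.default_rng(0)
        m = _matrix((rng.random((8, 80)) < 0.4).astype(int))
        r1 = bootstrap_support(m, 50, "link", seed=9)
        r2 = bootstrap_support(m, 50, "link", seed=9)
        assert r1.supports == r2.supports

    def test_iid_noise_has_no_strong_bipartitions(self):
        rng = np.random.default_rng(5)
        m = _matrix((rng.random((10, 200)) < 0.5).astype(int))
        res = bootstrap_support(m, 200, "link", seed=2)
        assert max(res.supports.values()) < 70.0


class TestLeafStability:
    def test_identical_trees_give_ls_one(self):
        data = np.zeros((6, 40), dtype=int)
        data[:3, :20] = 1
        data[3:, 20:] = 1
        m = _matrix(data)
        base = nj_tree(binary_distance(m, "link"))
        bs = BootstrapSet(taxa=[f"t{i}" for i in range(6)], trees=[base] * 4)
        ls = leaf_stability(bs)
        assert all(v == pytest.approx(1.0) for v in ls.values())

    def test_wandering_taxon_scores_lower(self):
        # taxon 'w' sits inside clade {a1,a2} in half the trees and inside
        # {b1,b2} in the other half; all other relations fixed
        def tree(w_with_a):
            a = TreeNode(children=[TreeNode(name="a1", length=1), TreeNode(name="a2", length=1)], length=1)
            b = TreeNode(children=[TreeNode(name="b1", length=1), TreeNode(name="b2", length=1)], length=1)
            w = TreeNode(name="w", length=1)
            if w_with_a:
                a = TreeNode(children=[a, w], length=1)
            else:
                b = TreeNode(children=[b, w], length=1)
            return TreeNode(children=[a, b, TreeNode(name="out", length=1)])

        trees = [tree(True)] * 3 + [tree(False)] * 3
        bs = BootstrapSet(taxa=["a1", "a2", "b1", "b2", "w", "out"], trees=trees)
        ls = leaf_stability(bs)
        assert ls["w"] < min(ls[t] for t in ("a1", "a2", "b1", "b2"))

    def test_matches_quartet_oracle_on_random_trees(self):
        # independent oracle: resolve each quartet by the four-point
        # condition on edge-count path distances
        rng = np.random.default_rng(21)
        ids = [f"t{i}" for i in range(5)]
        trees = []
        for _ in range(6):
            D = rng.random((5, 5))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            trees.append(nj_tree(DistanceMatrix(ids, D)))
        bs = BootstrapSet(taxa=ids, trees=trees)
        ls = leaf_stability(bs)

        def topo_dist(tree):
            def strip(node):
                for c in node.children:
                    c.length = 1.0
                    strip(c)
            strip(tree)
            return tree_path_lengths(tree)

        mats = [topo_dist(t) for t in trees]
        expected = {t: [] for t in ids}
        for quartet in itertools.combinations(ids, 4):
            counts = {0: 0, 1: 0, 2: 0}
            for pm in mats:
                a, b, c, d = quartet
                sums = [
                    pm.loc[a, b] + pm.loc[c, d],
                    pm.loc[a, c] + pm.loc[b, d],
                    pm.loc[a, d] + pm.loc[b, c],
                ]
                counts[int(np.argmin(sums))] += 1
            mx = max(counts.values()) / len(trees)
            for t in quartet:
                expected[t].append(mx)
        for t in ids:
            assert ls[t] == pytest.approx(np.mean(expected[t]))


class TestLineageMovement:
    @staticmethod
    def _tree(newick_like):
        """Build small fixed trees by nesting tuples of names."""

        def build(x):
            if isinstance(x, str):
                return TreeNode(name=x, length=1.0)
            return TreeNode(children=[build(c) for c in x], length=1.0)

        t = build(newick_like)
        t.length = None
        return t

    def test_query_always_inside_reference(self):
        t = self._tree((("q1", "q2"), ("r1", "r2"), "out"))
        # query {q1,q2} attaches next to reference {r1,r2} inside the clade
        t2 = self._tree(((("q1", "q2"), "r1"), "r2", "out"))
        bs = BootstrapSet(taxa=["q1", "q2", "r1", "r2", "out"], trees=[t2] * 5)
        lm = lineage_movement(bs, {"q1", "q2"}, {"r1", "r2"})
        assert lm.outside_pct == 0.0
        assert lm.inside_pct == 100.0

    def test_constructed_forty_percent_outside(self):
        inside = self._tree((((("q1", "q2"), "r1"), "r2"), "far", "out"))
        # query nested within the outgroup pair, away from the reference
        outside = self._tree(((("q1", "q2"), "out"), "far", ("r1", "r2")))
        bs = BootstrapSet(
            taxa=["q1", "q2", "r1", "r2", "out", "far"],
            trees=[inside, inside, inside, outside, outside],
        )
        lm = lineage_movement(bs, {"q1", "q2"}, {"r1", "r2"})
        assert lm.outside_pct == pytest.approx(40.0)
        assert lm.dispersed_pct == 0.0

    def test_non_monophyletic_query_counts_as_dispersed(self):
        t = self._tree((("q1", "r1"), ("q2", "r2"), "out"))
        bs = BootstrapSet(taxa=["q1", "q2", "r1", "r2", "out"], trees=[t] * 3)
        lm = lineage_movement(bs, {"q1", "q2"}, {"r1", "r2"})
        assert lm.dispersed_pct == 100.0

    def test_overlapping_query_reference_rejected(self):
        t = self._tree((("a", "b"), ("c", "d"), "e"))
        bs = BootstrapSet(taxa=["a", "b", "c", "d", "e"], trees=[t])
        with pytest.raises(ValueError, match="disjoint"):
            lineage_movement(bs, {"a"}, {"a", "b"})


class TestHomoplasyScan:
    def test_control_removal_changes_little(self):
        # removing a taxon with no conflicting signal leaves supports
        # within Monte-Carlo noise
        rng = np.random.default_rng(14)
        data = np.zeros((9, 300), dtype=int)
        data[:4, :150] = 1
        data[4:8, 150:] = 1
        data[8, :] = rng.random(300) < 0.5  # the taxon to remove: pure noise
        noise = (rng.random((9, 300)) < 0.03).astype(int)
        m = _matrix(data ^ noise)
        res = homoplasy_excess_scan(
            m, {"ctrl": {"t8"}}, n_reps=300, seed=3, method="link"
        )
        table = res["ctrl"].dropna()
        strong = table[table.support_before > 90]
        assert (strong.delta.abs() <= 6).all()
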