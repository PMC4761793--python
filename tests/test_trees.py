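"""Dice distance, NJ/UPGMA construction and bootstrap support."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from dartpop import (
    MarkerMatrix,
    bipartitions,
    bootstrap_support,
    dice_distance,
    neighbor_joining,
    upgma,
)
from .conftest import random_marker_matrix


def _mm(rows, groups=None):
    calls = pd.DataFrame(rows, dtype=float)
    calls.index = [f"i{k}" for k in range(len(rows))]
    calls.columns = [f"m{k}" for k in range(len(rows[0]))]
    g = None if groups is None else pd.Series(groups, index=calls.index)
    return MarkerMatrix(calls, g)


class TestDice:
    def test_hand_count(self):
        m = _mm([[1, 1, 0, 1], [1, 0, 0, 1]])
        d = dice_distance(m)
        assert d["i0", "i1"] == pytest.approx(0.2)

    def test_identical_and_disjoint(self):
        m = _mm([[1, 0], [1, 0], [0, 1]])
        d = dice_distance(m)
        assert d["i0", "i1"] == 0.0
        assert d["i0", "i2"] == 1.0

    def test_missing_calls_restrict_to_jointly_scored(self):
        m = _mm([[1, 1, np.nan], [1, 0, 1]])
        # joint loci: m0 (1,1), m1 (1,0) -> a=1, b=1, c=0 -> D = 1 - 2/3
        d = dice_distance(m)
        assert d["i0", "i1"] == pytest.approx(1 / 3)

    def test_no_shared_loci_is_error(self):
        m = _mm([[1, np.nan], [np.nan, 1]])
        with pytest.raises(ValueError, match="share no scored loci"):
            dice_distance(m)

    def test_all_absent_pair_is_zero_with_warning(self):
        m = _mm([[0, 0], [0, 0], [1, 1]])
        with pytest.warns(UserWarning, match="D set to 0"):
            d = dice_distance(m)
        assert d["i0", "i1"] == 0.0

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(0)
        m = random_marker_matrix(rng, n_ind=10, n_loci=30, missing_rate=0.05)
        d = dice_distance(m).data
        assert (d >= 0).all() and (d <= 1).all()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)


def _tree_distances(tree):
    """Leaf-to-leaf path lengths of a TreeNode."""
    tips = sorted(t.name for t in tree.tips())
    return {(a, b): tree.find(a).distance(tree.find(b)) for a in tips for b in tips if a < b}


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
                            ids=list("ABC"))
        t = neighbor_joining(dm)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths == pytest.approx({"A": 0.1, "B": 0.1, "C": 0.3})

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_distances_recovered_exactly(self, n_taxa):
        """NJ inverts distances generated from a known additive tree."""
        rng = np.random.default_rng(n_taxa)
        # random caterpillar tree with positive branch lengths
        ids = [f"t{i}" for i in range(n_taxa)]
        # build additive distances from a random binary tree via random splits
        from skbio import TreeNode

        newick = None
        if n_taxa == 4:
            newick = "((t0:0.11,t1:0.23):0.35,(t2:0.17,t3:0.29):0.05);"
        else:
            newick = "((t0:0.11,t1:0.23):0.31,((t2:0.17,t3:0.29):0.13,t4:0.41):0.07);"
        src = TreeNode.read([newick])
        d = np.zeros((n_taxa, n_taxa))
        for i in range(n_taxa):
            for j in range(i + 1, n_taxa):
                d[i, j] = d[j, i] = src.find(ids[i]).distance(src.find(ids[j]))
        t = neighbor_joining(DistanceMatrix(d, ids=ids))
        want = _tree_distances(src)
        got = _tree_distances(t)
        for pair, dist in want.items():
            assert got[pair] == pytest.approx(dist, abs=1e-12)
        assert bipartitions(t) == bipartitions(src)

    def test_fewer_than_three_labels_error(self):
        dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_deterministic_under_ties(self):
        d = np.full((5, 5), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, ids=list("abcde"))
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm)
        assert str(t1) == str(t2)
        for tip in t1.tips():
            assert tip.length >= 0

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = random_marker_matrix(rng, n_ind=7, n_loci=20)
            t = neighbor_joining(dice_distance(m))
            for node in t.traverse(include_self=False):
                assert node.length is None or node.length >= 0


def _is_ultrametric(tree, tol=1e-9):
    root = tree
    depths = [root.distance(tip) for tip in tree.tips()]
    return max(depths) - min(depths) <= tol


class TestUpgma:
    def test_hand_agglomeration(self):
        dm = DistanceMatrix(np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]]), ids=list("ABC"))
        t = upgma(dm)
        # (A,B) merged at height 1, joined with C at height 2
        a = t.find("A")
        assert a.length == pytest.approx(1.0)
        assert t.find("C").length == pytest.approx(2.0)
        assert a.parent.length == pytest.approx(1.0)
        assert _is_ultrametric(t)

    def test_two_labels_cherry(self):
        dm = DistanceMatrix(np.array([[0, 3.0], [3.0, 0]]), ids=["a", "b"])
        t = upgma(dm)
        assert t.find("a").length == pytest.approx(1.5)

    def test_ultrametric_input_recovered(self):
        # distances from a known ultrametric tree
        dm = DistanceMatrix(
            np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], float),
            ids=list("abcd"),
        )
        t = upgma(dm)
        got = _tree_distances(t)
        for (x, y), v in got.items():
            assert v == pytest.approx(dm[x, y], abs=1e-12)

    def test_random_matrices_are_ultrametric(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(3, 9))
            x = rng.random((n, n))
            d = (x + x.T) / 2
            np.fill_diagonal(d, 0)
            t = upgma(DistanceMatrix(d, ids=[f"x{i}" for i in range(n)]))
            assert _is_ultrametric(t)


class TestBootstrap:
    def test_identical_individuals_get_full_support(self):
        rng = np.random.default_rng(8)
        calls = (rng.random((6, 40)) < 0.5).astype(float)
        calls[1] = calls[0]  # identical pair
        m = _mm(calls.tolist())
        t = bootstrap_support(m, n_reps=200, seed=0)
        cherry = t.find("i0").parent
        names = {tip.name for tip in cherry.tips()}
        if names == {"i0", "i1"}:
            assert float(cherry.name) == 100.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        m = random_marker_matrix(rng, n_ind=6, n_loci=25)
        t1 = bootstrap_support(m, n_reps=50, seed=7)
        t2 = bootstrap_support(m, n_reps=50, seed=7)
        assert str(t1) == str(t2)

    def test_separated_clusters_strong_support(self):
        from dartpop import PopulationSpec, generate_markers

        spec = PopulationSpec(sizes=(5, 5), n_loci=200, fst=0.5)
        m, _ = generate_markers(spec, seed=4)
        t = bootstrap_support(m, n_reps=100, seed=5)
        split = frozenset(i for i in m.individuals if i.startswith("pop1"))
        leaves = frozenset(m.individuals)
        key = min(split, leaves - split, key=lambda s: (len(s), sorted(s)))
        supports = {
            frozenset(min((frozenset(x.name for x in nd.tips()),
                           leaves - frozenset(x.name for x in nd.tips())),
                          key=lambda s: (len(s), sorted(s)))): float(nd.name)
            for nd in t.non_tips(include_self=False) if nd.name is not None
        }
        assert supports.get(key, 0.0) >= 95.0

    def test_too_few_polymorphic_loci_error(self):
        m = _mm([[1, 1], [1, 1], [1, 0]])
        with pytest.raises(ValueError, match="polymorphic"):
            bootstrap_support(m, n_reps=10, seed=0)
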