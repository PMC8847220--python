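"""Distance trees: oracle checks against independent implementations,
additive/ultrametric exactness, RF metric properties, rooting."""

import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj
from skbio.tree import upgma as skbio_upgma

from dnvphylo import (
    LabeledMatrix,
    bionj_tree,
    build_tree,
    nj_tree,
    read_newick,
    robinson_foulds,
    root_with_outgroup,
    upgma_tree,
    write_newick,
)
from dnvphylo.phylo import newick_string

ADDITIVE = LabeledMatrix(
    list("ABCD"),
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
)
ULTRAMETRIC = LabeledMatrix(
    list("ABCD"),
    [[0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]],
)


def _random_tree(rng, n_leaves, blen_low=0.5, blen_high=1.5):
    """Random binary tree by random agglomeration, unit-order labels."""
    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(blen_low, blen_high))
        b.length = float(rng.uniform(blen_low, blen_high))
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def _path_matrix(tree) -> LabeledMatrix:
    dm = tree.tip_tip_distances()
    labels = list(dm.ids)
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    values = dm.data[np.ix_(order, order)]
    return LabeledMatrix([labels[i] for i in order], values)


class TestUpgma:
    def test_hand_agglomeration_heights(self):
        tree = upgma_tree(
            LabeledMatrix(
                list("ABCD"),
                [[0, 2, 4, 6], [2, 0, 4, 6], [4, 4, 0, 6], [6, 6, 6, 0]],
            )
        )
        # (((A,B),C),D) with merge heights 1, 2, 3
        assert newick_string(tree) == "(((A:1.0,B:1.0):1.0,C:2.0):1.0,D:3.0);"

    def test_two_taxa_cherry(self):
        tree = upgma_tree(LabeledMatrix(["A", "B"], [[0, 3], [3, 0]]))
        assert newick_string(tree) == "(A:1.5,B:1.5);"

    @given(st.integers(0, 200))
    def test_ultrametric_input_reconstructed_exactly(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        # ultrametric by construction: random UPGMA-style merge heights
        tree = upgma_tree(_random_ultrametric(rng, n))
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert max(depths.values()) == pytest.approx(min(depths.values()))

    def test_matches_skbio_upgma_topology(self):
        rng = np.random.default_rng(11)
        m = _perturbed_matrix(rng, 7)
        mine = upgma_tree(m)
        ref = skbio_upgma(DistanceMatrix(m.values, m.labels))
        assert robinson_foulds(mine, ref) == 0


def _random_ultrametric(rng, n) -> LabeledMatrix:
    """Random ultrametric matrix via a random clock tree's path distances."""
    # random clock tree: merge clusters at increasing heights
    heights = np.sort(rng.uniform(0.5, 5.0, size=n - 1))
    clusters = [{i} for i in range(n)]
    d = np.zeros((n, n))
    for h in heights:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        cj = clusters.pop(j)
        ci = clusters.pop(i)
        for a in ci:
            for b in cj:
                d[a, b] = d[b, a] = 2 * h
        clusters.append(ci | cj)
    return LabeledMatrix([f"L{i}" for i in range(n)], d)


def _perturbed_matrix(rng, n, noise=0.05) -> LabeledMatrix:
    tree = _random_tree(rng, n)
    m = _path_matrix(tree)
    eps = rng.normal(0, noise, size=(n, n))
    eps = (eps + eps.T) / 2
    np.fill_diagonal(eps, 0)
    values = np.clip(m.values + eps, 0.01, None)
    np.fill_diagonal(values, 0)
    return LabeledMatrix(m.labels, values)


class TestNeighborJoining:
    def test_additive_four_taxon_exact_branch_lengths(self):
        tree = nj_tree(ADDITIVE)
        assert newick_string(tree) == "((A:1.0,B:2.0):1.0,C:3.0,D:4.0);"

    def test_three_taxa_closed_form(self):
        m = LabeledMatrix(list("ABC"), [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_tree(m)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    @given(st.integers(0, 200))
    def test_additive_matrices_reconstructed_within_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        m = _path_matrix(_random_tree(rng, n))
        back = _path_matrix(nj_tree(m))
        assert back.labels == m.labels
        assert back.values == pytest.approx(m.values, abs=1e-9)

    def test_matches_skbio_nj_topology_on_noisy_matrix(self):
        rng = np.random.default_rng(5)
        m = _perturbed_matrix(rng, 8)
        mine = nj_tree(m)
        ref = skbio_nj(DistanceMatrix(m.values, m.labels))
        assert robinson_foulds(mine, ref) == 0


class TestBionj:
    def test_additive_input_agrees_with_nj(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = _path_matrix(_random_tree(rng, int(rng.integers(4, 9))))
            assert robinson_foulds(bionj_tree(m), nj_tree(m)) == 0

    def test_additive_reconstruction_exact(self):
        back = _path_matrix(bionj_tree(ADDITIVE))
        assert back.values == pytest.approx(ADDITIVE.values, abs=1e-9)

    def test_three_taxa_same_as_nj(self):
        m = LabeledMatrix(list("ABC"), [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        assert newick_string(bionj_tree(m)) == newick_string(nj_tree(m))

    def test_recovers_topology_under_noise(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1_000 + seed)
            tree = _random_tree(rng, 8)
            m = _perturbed_matrix_from(tree, rng)
            hits += robinson_foulds(bionj_tree(m), tree) == 0
        assert hits >= 90

    def test_agrees_with_r_ape_bionj(self, tmp_path):
        rng = np.random.default_rng(17)
        m = _perturbed_matrix(rng, 7)
        mat_path = tmp_path / "m.tsv"
        from dnvphylo.matrix import write_matrix

        write_matrix(m, mat_path)
        out_path = tmp_path / "ape.nwk"
        script = (
            f'd <- as.matrix(read.table("{mat_path}", sep="\\t", header=TRUE, '
            'row.names=1, check.names=FALSE)); '
            "library(ape); "
            f'write.tree(bionj(as.dist(d)), "{out_path}")'
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        assert robinson_foulds(bionj_tree(m), read_newick(out_path)) == 0


def _perturbed_matrix_from(tree, rng, noise=0.05) -> LabeledMatrix:
    m = _path_matrix(tree)
    n = len(m)
    eps = rng.normal(0, noise, size=(n, n))
    eps = (eps + eps.T) / 2
    np.fill_diagonal(eps, 0)
    values = np.clip(m.values + eps, 0.01, None)
    np.fill_diagonal(values, 0)
    return LabeledMatrix(m.labels, values)


class TestScalingInvariance:
    @pytest.mark.parametrize("method", ["upgma", "nj", "bionj"])
    def test_topology_unchanged_lengths_scaled(self, method):
        rng = np.random.default_rng(23)
        m = _perturbed_matrix(rng, 6)
        scaled = LabeledMatrix(m.labels, m.values * 3.5)
        t1 = build_tree(m, method)
        t2 = build_tree(scaled, method)
        assert robinson_foulds(t1, t2) == 0
        l1 = sorted(t.length for t in t1.tips())
        l2 = sorted(t.length for t in t2.tips())
        assert l2 == pytest.approx([3.5 * x for x in l1])


class TestRooting:
    def test_outgroup_becomes_root_child_and_splits_preserved(self):
        tree = nj_tree(ADDITIVE)
        rooted = root_with_outgroup(tree, "D")
        root_children = {
            (t.name if t.is_tip() else None) for t in rooted.children
        }
        assert "D" in root_children
        assert robinson_foulds(rooted, tree) == 0

    def test_rooting_twice_idempotent_topology(self):
        tree = nj_tree(ADDITIVE)
        once = root_with_outgroup(tree, "D")
        twice = root_with_outgroup(once, "D")
        assert robinson_foulds(once, twice) == 0

    def test_absent_label_is_error(self):
        with pytest.raises(ValueError):
            root_with_outgroup(nj_tree(ADDITIVE), "Z")


class TestRobinsonFoulds:
    def test_identity(self):
        t = nj_tree(ADDITIVE)
        assert robinson_foulds(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = TreeNode.read(["((A,B),(C,D));"])
        t2 = TreeNode.read(["((A,C),(B,D));"])
        assert robinson_foulds(t1, t2) == 2

    def test_leaf_set_mismatch_is_error(self):
        t1 = TreeNode.read(["((A,B),(C,D));"])
        t2 = TreeNode.read(["((A,B),(C,E));"])
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)

    @given(st.integers(0, 100))
    @settings(max_examples=25)
    def test_metric_properties_against_dendropy(self, seed):
        import dendropy
        from dendropy.calculate import treecompare

        rng = np.random.default_rng(seed)
        trees = [_random_tree(rng, 7) for _ in range(3)]
        rf = [
            [robinson_foulds(a, b) for b in trees] for a in trees
        ]
        # symmetry, identity, triangle inequality
        for i in range(3):
            assert rf[i][i] == 0
            for j in range(3):
                assert rf[i][j] == rf[j][i]
                for k in range(3):
                    assert rf[i][j] <= rf[i][k] + rf[k][j]
        # agreement with dendropy's unrooted symmetric difference
        tns = dendropy.TaxonNamespace()
        dtrees = [
            dendropy.Tree.get(
                data=newick_string(t), schema="newick", taxon_namespace=tns
            )
            for t in trees
        ]
        for dt in dtrees:
            dt.encode_bipartitions()
        assert rf[0][1] == treecompare.symmetric_difference(dtrees[0], dtrees[1])
        assert rf[0][2] == treecompare.symmetric_difference(dtrees[0], dtrees[2])


class TestNewickIO:
    def test_two_leaf_serialization(self, tmp_path):
        tree = TreeNode.read(["(A:1.0,B:2.0);"])
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        assert p.read_text().strip() == "(A:1.0,B:2.0);"

    @given(st.integers(0, 100))
    @settings(max_examples=25)
    def test_round_trip_preserves_topology(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        tree = _random_tree(rng, 8)
        p = tmp_path_factory.mktemp("nwk") / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert {t.name for t in back.tips()} == {t.name for t in tree.tips()}
        assert robinson_foulds(tree, back) == 0

    def test_duplicate_leaves_refused(self, tmp_path):
        tree = TreeNode.read(["((A:1,A:1):1,B:2);"])
        with pytest.raises(ValueError):
            write_newick(tree, tmp_path / "bad.nwk")
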