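import numpy as np
import pytest

from nemaclock.align import MSA
from nemaclock.phylo import (
    DistanceMatrix,
    TreeNode,
    bipartitions,
    bootstrap,
    build_concatemer,
    gamma_correct,
    neighbor_joining,
    nj_tree,
    p_distance,
    poisson_correct,
    read_newick,
    write_newick,
)


# ---------------------------------------------------------------------------
# helpers: random additive trees and their leaf-distance matrices
# ---------------------------------------------------------------------------


def random_tree(n_taxa, rng, min_bl=0.1, max_bl=1.0):
    nodes = [TreeNode(name=f"t{i:02d}", length=float(rng.uniform(min_bl, max_bl))) for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(
            length=float(rng.uniform(min_bl, max_bl)), children=[nodes[i], nodes[j]]
        )
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    return TreeNode(children=nodes)


def leaf_distance_matrix(tree):
    parent = {}
    for node in tree.preorder():
        for c in node.children:
            parent[id(c)] = node
    leaves = tree.leaves()
    names = [l.name for l in leaves]

    def path_up(leaf):
        out, node, d = {}, leaf, 0.0
        while id(node) in parent:
            d += node.length
            node = parent[id(node)]
            out[id(node)] = d
        return out

    paths = [path_up(l) for l in leaves]
    n = len(leaves)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = [k for k in paths[i] if k in paths[j]]
            D[i, j] = D[j, i] = min(paths[i][k] + paths[j][k] for k in shared)
    return names, D


def edge_lengths_by_split(tree):
    """bipartition -> branch length, plus leaf name -> pendant length."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    internal, pendant = {}, {}
    for node in tree.preorder():
        if node is tree:
            continue
        if node.is_leaf():
            pendant[node.name] = node.length
            continue
        side = frozenset(node.leaf_names())
        key = side if anchor not in side else all_leaves - side
        if len(side) >= 2 and len(all_leaves - side) >= 2:
            internal[key] = node.length
    return internal, pendant


class TestPDistance:
    def test_identical_rows_have_zero_distance(self):
        d = p_distance(MSA([("a", "MKVL"), ("b", "MKVL")]))
        assert d.matrix[0, 1] == 0.0

    def test_pairwise_deletion_excludes_gap_sites(self):
        d = p_distance(MSA([("a", "AC-G"), ("b", "ACTG")]))
        assert d.usable_sites[0, 1] == 3
        assert d.matrix[0, 1] == 0.0

    def test_hand_counted_alignment(self):
        rows = [
            ("w", "MKVLAHEWQRTSACDEFGHI"),
            ("x", "MKVLGHEWQRTSACDEFGHI"),
            ("y", "MKV-AHEWQRTSACDEFGH-"),
            ("z", "MKVLAHEWQRTSACDEWGHI"),
        ]
        d = p_distance(MSA(rows))
        assert d.matrix[0, 1] == pytest.approx(1 / 20)  # w vs x: 1 diff / 20
        assert d.matrix[0, 2] == pytest.approx(0 / 18)  # w vs y: gaps excluded
        assert d.matrix[1, 3] == pytest.approx(2 / 20)  # x vs z: G5 and W17
        assert d.usable_sites[0, 2] == 18

    def test_no_usable_sites_is_an_error_naming_the_pair(self):
        with pytest.raises(ValueError, match="a.*b"):
            p_distance(MSA([("a", "MK--"), ("b", "--VL")]))


class TestCorrections:
    def test_poisson_closed_forms(self):
        assert poisson_correct(0.0) == 0.0
        assert poisson_correct(0.5) == pytest.approx(np.log(2))
        assert poisson_correct(0.999) > 6.0
        with pytest.raises(ValueError):
            poisson_correct(1.0)

    def test_gamma_closed_forms(self):
        assert gamma_correct(0.5, 1.0) == pytest.approx(1.0)
        assert gamma_correct(0.0, 3.7) == 0.0
        with pytest.raises(ValueError):
            gamma_correct(0.5, 0.0)
        with pytest.raises(ValueError):
            gamma_correct(1.0, 1.0)

    def test_gamma_tends_to_poisson_for_large_alpha(self):
        for p in np.arange(0.1, 0.95, 0.1):
            g = gamma_correct(p, 1e6)
            assert abs(g - poisson_correct(p)) / poisson_correct(p) < 1e-4

    def test_corrections_increase_with_p_and_exceed_p(self):
        ps = np.linspace(0.01, 0.9, 30)
        d = poisson_correct(ps)
        assert np.all(np.diff(d) > 0) and np.all(d >= ps)
        g = gamma_correct(ps, 0.5)
        assert np.all(np.diff(g) > 0)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(["a", "b", "c"], D)
        lens = {l.name: l.length for l in tree.leaves()}
        assert lens["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lens["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lens["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(["a", "b"], np.zeros((2, 2)))

    def test_recovers_additive_trees_exactly(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            true = random_tree(n, rng)
            names, D = leaf_distance_matrix(true)
            rec = nj_tree(names, D)
            ti, tp = edge_lengths_by_split(true)
            ri, rp = edge_lengths_by_split(rec)
            assert set(ti) == set(ri)
            for k in ti:
                assert ti[k] == pytest.approx(ri[k], abs=1e-9)
            for k in tp:
                assert tp[k] == pytest.approx(rp[k], abs=1e-9)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(23)
        true = random_tree(7, rng)
        names, D = leaf_distance_matrix(true)
        t1 = nj_tree(names, D)
        perm = rng.permutation(len(names))
        t2 = nj_tree([names[i] for i in perm], D[np.ix_(perm, perm)])
        assert set(bipartitions(t1)) == set(bipartitions(t2))

    def test_distance_matrix_wrapper_validates(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 1.5], [2, 1.5, 0]]))
        assert neighbor_joining(dm).leaf_names()


class TestBootstrap:
    def _clean_alignment(self):
        # three pairs, each split backed by ten clean synapomorphies, plus
        # constant columns so no sequence pair is saturated
        const = "M" * 10
        return MSA(
            [
                ("a1", const + "A" * 10 + "C" * 10),
                ("a2", const + "A" * 10 + "C" * 10),
                ("b1", const + "G" * 10 + "C" * 10),
                ("b2", const + "G" * 10 + "C" * 10),
                ("c1", const + "G" * 10 + "Y" * 10),
                ("c2", const + "G" * 10 + "Y" * 10),
            ]
        )

    def test_clean_synapomorphies_give_full_support(self):
        tree = bootstrap(self._clean_alignment(), n=50, seed=0)
        sups = [n.support for n in tree.preorder() if n.support is not None]
        assert sups and all(s == 100.0 for s in sups)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = bootstrap(self._clean_alignment(), n=1, seed=3)
        for node in tree.preorder():
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_fixed_seed_reproducible(self):
        t1 = bootstrap(self._clean_alignment(), n=20, seed=5)
        t2 = bootstrap(self._clean_alignment(), n=20, seed=5)
        assert write_newick(t1) == write_newick(t2)

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap(self._clean_alignment(), n=0, seed=0)


class TestConcatemer:
    def test_lengths_add_up(self):
        a1 = MSA([("x_g1", "MKVLAHEWQR"), ("y_g1", "MKVLAHEWQR")])
        a2 = MSA([("x_g2", "ACDEFGHIKLMNPQW"), ("y_g2", "ACDEFGHIKLMNPQW")])
        cat = build_concatemer(
            {"g1": a1, "g2": a2},
            {"x": {"g1": "x_g1", "g2": "x_g2"}, "y": {"g1": "y_g1", "g2": "y_g2"}},
        )
        assert cat.ncols == 25

    def test_missing_species_is_gap_filled(self):
        a1 = MSA([("x_g1", "MKVL"), ("y_g1", "MKVL")])
        a2 = MSA([("x_g2", "ACDE")])
        cat = build_concatemer(
            {"g1": a1, "g2": a2},
            {"x": {"g1": "x_g1", "g2": "x_g2"}, "y": {"g1": "y_g1"}},
        )
        assert cat.row("y") == "MKVL----"

    def test_species_absent_everywhere_is_an_error(self):
        a1 = MSA([("x_g1", "MKVL")])
        with pytest.raises(ValueError):
            build_concatemer({"g1": a1}, {"z": {}})

    def test_distances_match_single_alignment_of_same_columns(self):
        rows = [("x", "MKVLAHEW"), ("y", "MKVAAHEW"), ("z", "MKVLGHEW")]
        single = MSA(rows)
        half1 = MSA([(f"{i}_g1", s[:4]) for i, s in rows])
        half2 = MSA([(f"{i}_g2", s[4:]) for i, s in rows])
        cat = build_concatemer(
            {"g1": half1, "g2": half2},
            {i: {"g1": f"{i}_g1", "g2": f"{i}_g2"} for i, _ in rows},
        )
        np.testing.assert_allclose(p_distance(cat).matrix, p_distance(single).matrix)


class TestNewick:
    def test_round_trip_preserves_topology_lengths_and_supports(self):
        rng = np.random.default_rng(31)
        tree = random_tree(8, rng)
        for i, node in enumerate(tree.preorder()):
            if not node.is_leaf() and node is not tree:
                node.support = float(10 * i % 101)
        text = write_newick(tree)
        back = read_newick(text)
        ti, tp = edge_lengths_by_split(tree)
        ri, rp = edge_lengths_by_split(back)
        assert set(ti) == set(ri)
        for k in ti:
            assert ti[k] == pytest.approx(ri[k], abs=1e-9)
        sup_t = {k: n.support for k, n in bipartitions(tree).items()}
        sup_r = {k: n.support for k, n in bipartitions(back).items()}
        assert sup_t == sup_r
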