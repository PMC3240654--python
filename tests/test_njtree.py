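"""Neighbor joining, bootstrap supports, Newick I/O, monophyly."""

import numpy as np
import pytest

import phylopop as pp
from phylopop.njtree import path_lengths, root_at

from conftest import CPWP, EP


def random_additive_case(n, seed):
    """A random binary tree (random joins, random lengths) and its
    leaf-to-leaf path-length matrix — the additivity oracle."""
    rng = np.random.default_rng(seed)
    nodes = [pp.njtree.Node(name=f"t{i}") for i in range(n)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 1.0))
    active = list(nodes)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]
        parent = pp.njtree.Node(children=[a, b], length=float(rng.uniform(0.05, 1.0)))
        active = [x for x in active if x is not a and x is not b] + [parent]
    tree = pp.Tree(root=pp.njtree.Node(children=active))
    paths = path_lengths(tree)
    names = sorted(tree.leaf_names())
    d = np.zeros((n, n))
    for a_idx, a in enumerate(names):
        for b_idx in range(a_idx + 1, n):
            b = names[b_idx]
            d[a_idx, b_idx] = d[b_idx, a_idx] = paths[(a, b)]
    matrix = pp.DistanceMatrix(ids=names, d=d, L=np.full((n, n), 1000))
    return tree, matrix


def splits(tree):
    return set(tree.bipartitions())


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.2, 0.3], [0.2, 0.0, 0.4], [0.3, 0.4, 0.0]])
        matrix = pp.DistanceMatrix(ids=["A", "B", "C"], d=d, L=np.full((3, 3), 100))
        tree = pp.neighbor_joining(matrix)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})
        assert tree.to_newick() == "(A:0.050000,B:0.150000,C:0.250000);"

    @pytest.mark.parametrize("n", [4, 5, 6, 8])
    def test_exact_on_additive_matrices(self, n):
        for seed in range(20):
            true_tree, matrix = random_additive_case(n, seed)
            recovered = pp.neighbor_joining(matrix)
            assert splits(recovered) == splits(true_tree)
            rec_paths = path_lengths(recovered)
            for pair, expected in path_lengths(true_tree).items():
                assert rec_paths[pair] == pytest.approx(expected, abs=1e-9)

    def test_16s_east_pacific_clade(self, aln16s, matrix16s):
        tree = pp.neighbor_joining(matrix16s)
        ep_ids = {aln16s.ids[i] for i in aln16s.group_indices(EP)}
        assert tree.is_monophyletic(ep_ids)
        cw_ids = {aln16s.ids[i] for i in aln16s.group_indices(CPWP)}
        assert tree.is_monophyletic(cw_ids)

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        for seed in range(5):
            _, matrix = random_additive_case(7, seed + 500)
            sk_dm = skbio.DistanceMatrix(matrix.d, ids=matrix.ids)
            sk_tree = skbio.tree.nj(sk_dm)
            all_leaves = frozenset(matrix.ids)
            anchor = min(all_leaves)
            sk_splits = set()
            for subset in sk_tree.subsets():
                side = frozenset(subset)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    sk_splits.add(side if anchor not in side else all_leaves - side)
            ours = splits(pp.neighbor_joining(matrix))
            assert ours <= sk_splits

    def test_taxon_order_invariance_without_ties(self):
        """With unique Q minima the input taxon order is irrelevant."""
        rng = np.random.default_rng(42)
        _, matrix = random_additive_case(7, 99)
        perm = list(rng.permutation(matrix.n))
        shuffled = matrix.submatrix(perm)
        assert splits(pp.neighbor_joining(matrix)) == splits(
            pp.neighbor_joining(shuffled)
        )

    def test_lengths_are_clamped_nonnegative(self, matrix16s):
        def walk(node):
            if node.length is not None:
                assert node.length >= 0.0
            for child in node.children:
                walk(child)

        walk(pp.neighbor_joining(matrix16s).root)

    def test_too_few_taxa(self):
        matrix = pp.DistanceMatrix(ids=["a", "b"], d=np.zeros((2, 2)), L=np.ones((2, 2)))
        with pytest.raises(pp.InputError):
            pp.neighbor_joining(matrix)


class TestBootstrapSupport:
    def test_single_replicate_supports_are_binary(self, aln16s):
        tree, _ = pp.bootstrap_support(aln16s, B=1, seed=0)
        supports = [n.support for n in tree.bipartitions().values()]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_ten_fixed_sites_give_full_support(self):
        base = "ACGTACGTACGTACGTACGTACGTACGTAC"  # L = 30
        flipped = list(base)
        for col in range(10):
            flipped[col] = {"A": "G", "C": "T", "G": "A", "T": "C"}[flipped[col]]
        flipped = "".join(flipped)
        aln = pp.Alignment(
            ids=["a1", "a2", "b1", "b2"],
            seqs=[base, base, flipped, flipped],
            group=["x", "x", "y", "y"],
        )
        tree, _ = pp.bootstrap_support(aln, B=200, seed=0)
        (node,) = tree.bipartitions().values()
        assert node.support >= 99.0

    def test_16s_regional_split_is_strongly_supported(self, aln16s):
        tree, redrawn = pp.bootstrap_support(aln16s, B=200, seed=5)
        ep_ids = frozenset(aln16s.ids[i] for i in aln16s.group_indices(EP))
        all_leaves = frozenset(aln16s.ids)
        canonical = ep_ids if min(all_leaves) not in ep_ids else all_leaves - ep_ids
        node = tree.bipartitions()[canonical]
        assert node.support >= 90.0
        assert redrawn == 0

    def test_supports_reproducible_for_fixed_seed(self, aln16s):
        def run():
            tree, _ = pp.bootstrap_support(aln16s, B=50, seed=9)
            return {
                frozenset(k): n.support for k, n in tree.bipartitions().items()
            }

        assert run() == run()


class TestNewick:
    def test_round_trip_preserves_splits_and_lengths(self, matrix16s, tmp_path):
        tree = pp.neighbor_joining(matrix16s)
        path = tmp_path / "tree.nwk"
        pp.write_newick(tree, path)
        back = pp.read_newick(path)
        assert set(back.leaf_names()) == set(tree.leaf_names())
        assert splits(back) == splits(tree)
        orig = path_lengths(tree)
        for pair, dist in path_lengths(back).items():
            assert dist == pytest.approx(orig[pair], abs=1e-5)

    def test_supports_round_trip_as_internal_labels(self, aln16s, tmp_path):
        tree, _ = pp.bootstrap_support(aln16s, B=20, seed=0)
        path = tmp_path / "tree.nwk"
        pp.write_newick(tree, path)
        back = pp.read_newick(path)
        orig = {k: n.support for k, n in tree.bipartitions().items()}
        parsed = {k: n.support for k, n in back.bipartitions().items()}
        assert parsed == orig

    def test_dendropy_parses_our_output(self, matrix16s):
        dendropy = pytest.importorskip("dendropy")
        newick = pp.neighbor_joining(matrix16s).to_newick()
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        assert {t.label for t in tree.taxon_namespace} == set(matrix16s.ids)

    @pytest.mark.parametrize("bad", ["(A,B;", "(A,B))C;", "(A,B)", "(A:x,B:1);"])
    def test_malformed_newick_rejected(self, bad):
        with pytest.raises(pp.NewickError):
            pp.read_newick(bad)


class TestMonophylyAndRooting:
    def test_single_leaf_and_complement(self, matrix16s):
        tree = pp.neighbor_joining(matrix16s)
        leaves = tree.leaf_names()
        assert tree.is_monophyletic({leaves[0]})
        assert tree.is_monophyletic(set(leaves[1:]))

    def test_unknown_leaf_rejected(self, matrix16s):
        tree = pp.neighbor_joining(matrix16s)
        with pytest.raises(pp.InputError):
            tree.is_monophyletic({"not-a-leaf"})

    def test_rooting_preserves_path_lengths(self, matrix16s):
        tree = pp.neighbor_joining(matrix16s)
        rooted = root_at(tree, tree.leaf_names()[3])
        orig = path_lengths(tree)
        for pair, dist in path_lengths(rooted).items():
            assert dist == pytest.approx(orig[pair], abs=1e-9)
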