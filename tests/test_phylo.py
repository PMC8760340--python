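"""Distances, neighbor joining, bootstrap and monophyly.

The NJ oracle is tree simulation: random binary trees with random branch
lengths induce additive distance matrices whose generating topology NJ
must recover exactly (compared as bipartition sets).
"""

import math
from io import StringIO

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from cdmine import phylo
from cdmine.seqio import AlignedRecord
from cdmine.synthetic_data import evolve_family, _rand_protein


class TestProteinDistance:
    def test_identical_pair_distance_zero(self):
        dm = phylo.protein_distance([AlignedRecord("a", "ACDEF"), AlignedRecord("b", "ACDEF")])
        assert dm["a", "b"] == 0.0

    def test_poisson_correction_closed_form(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        dm = phylo.protein_distance([AlignedRecord("a", a), AlignedRecord("b", b)])
        assert dm["a", "b"] == pytest.approx(-math.log(0.9), abs=1e-12)

    def test_gap_columns_excluded(self):
        a = "AC--EF"
        b = "AC-DEW"
        dm = phylo.protein_distance([AlignedRecord("a", a), AlignedRecord("b", b)])
        # shared columns: positions 1,2,5,6 -> one mismatch of four
        assert dm["a", "b"] == pytest.approx(-math.log(0.75))

    def test_no_shared_columns_is_an_error(self):
        with pytest.raises(ValueError, match="share no aligned columns"):
            phylo.protein_distance([AlignedRecord("a", "AA--"), AlignedRecord("b", "--CC")])

    def test_saturated_pair_is_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            dm = phylo.protein_distance(
                [AlignedRecord("a", "A" * 50), AlignedRecord("b", "C" * 50)])
        assert dm["a", "b"] == pytest.approx(-math.log(1 - 0.95))


def _random_additive_case(rng, n_taxa):
    """Random binary tree -> (leaf path-distance matrix, bipartition set)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = {t: None for t in taxa}  # leaf -> parent chain built below
    # build a random topology by sequential joining; track leaf sets & edges
    clades = [frozenset([t]) for t in taxa]
    children = {c: [] for c in clades}
    lengths = {}
    while len(clades) > 2:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        a, b = clades[i], clades[j]
        parent = a | b
        children[parent] = [a, b]
        lengths[a] = float(rng.uniform(0.1, 1.0))
        lengths[b] = float(rng.uniform(0.1, 1.0))
        clades = [c for k, c in enumerate(clades) if k not in (i, j)] + [parent]
    lengths[clades[0]] = float(rng.uniform(0.1, 1.0))
    lengths[clades[1]] = float(rng.uniform(0.1, 1.0))
    root = frozenset(taxa)
    children[root] = [clades[0], clades[1]]

    # leaf-to-leaf path distances
    def path_to_root(leaf):
        out = {}
        def descend(clade, acc):
            if leaf in clade:
                if clade != root:
                    out[clade] = acc
                for ch in children.get(clade, []):
                    descend(ch, acc)
        # accumulate from root down: distance from leaf up = sum of lengths
        # of clades on the path containing the leaf (excluding root)
        path = [c for c in lengths if leaf in c]
        return path
    d = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            px = {c for c in lengths if taxa[x] in c}
            py = {c for c in lengths if taxa[y] in c}
            sym = px.symmetric_difference(py)
            d[x, y] = d[y, x] = sum(lengths[c] for c in sym)
    bips = {phylo.canonical_bipartition(c, root)
            for c in lengths if 1 < len(c) < n_taxa - 1}
    return DistanceMatrix(d, taxa), bips


def test_nj_recovers_generating_topology_on_random_additive_matrices():
    rng = np.random.default_rng(99)
    for rep in range(200):
        n = int(rng.integers(4, 9))
        dm, true_bips = _random_additive_case(rng, n)
        tree = phylo.nj_tree(dm)
        assert phylo.edge_bipartitions(tree) == true_bips, rep


def test_three_taxon_closed_form():
    d_ab, d_ac, d_bc = 0.4, 0.6, 0.8
    dm = DistanceMatrix(np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]]),
                        ["A", "B", "C"])
    tree = phylo.nj_tree(dm)
    got = {leaf.name: leaf.length for leaf in tree.tips()}
    assert got["A"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
    assert got["B"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
    assert got["C"] == pytest.approx((d_ac + d_bc - d_ab) / 2)


def test_equal_distances_give_deterministic_tree():
    d = np.ones((4, 4)) - np.eye(4)
    dm = DistanceMatrix(d, list("ABCD"))
    assert str(phylo.nj_tree(dm)) == str(phylo.nj_tree(dm))


def test_too_few_taxa_rejected():
    dm = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ["a", "b"])
    with pytest.raises(ValueError):
        phylo.nj_tree(dm)


def _two_clade_family(n_a=4, n_b=4, between=0.8, within=0.05, seed=21):
    names_a = [f"A{i}" for i in range(n_a)]
    names_b = [f"B{i}" for i in range(n_b)]
    nwk = ("(({}):{},({}):{});".format(
        ",".join(f"{n}:{within}" for n in names_a), between / 2,
        ",".join(f"{n}:{within}" for n in names_b), between / 2))
    tree = TreeNode.read(StringIO(nwk))
    root = _rand_protein(np.random.default_rng(seed), 300)
    return evolve_family(root, tree, rate=1.0, seed=seed), set(names_a)


class TestBootstrap:
    def test_deep_split_gets_full_support(self):
        fam, clade_a = _two_clade_family()
        phy = phylo.bootstrap_support(fam, n_reps=100, seed=3)
        ok, support = phylo.is_monophyletic(phy, clade_a)
        assert ok and support == 100.0

    def test_single_replicate_supports_are_binary(self):
        fam, _ = _two_clade_family()
        phy = phylo.bootstrap_support(fam, n_reps=1, seed=4)
        assert set(phy.supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        fam, _ = _two_clade_family()
        p1 = phylo.bootstrap_support(fam, n_reps=20, seed=5)
        p2 = phylo.bootstrap_support(fam, n_reps=20, seed=5)
        assert p1.supports == p2.supports

    def test_supports_within_bounds(self):
        fam, _ = _two_clade_family()
        phy = phylo.bootstrap_support(fam, n_reps=25, seed=6)
        assert all(0.0 <= v <= 100.0 for v in phy.supports.values())


class TestMonophyly:
    def test_full_taxon_set_and_singletons_are_trivially_monophyletic(self):
        fam, clade_a = _two_clade_family()
        phy = phylo.bootstrap_support(fam, n_reps=5, seed=7)
        assert phylo.is_monophyletic(phy, {r.id for r in fam}) == (True, 100.0)
        assert phylo.is_monophyletic(phy, {"A0"}) == (True, 100.0)

    def test_mixed_labelset_is_not_monophyletic(self):
        fam, _ = _two_clade_family()
        phy = phylo.bootstrap_support(fam, n_reps=5, seed=8)
        ok, _ = phylo.is_monophyletic(phy, {"A0", "B0"})
        assert not ok

    def test_unknown_label_rejected(self):
        fam, _ = _two_clade_family()
        phy = phylo.bootstrap_support(fam, n_reps=1, seed=9)
        with pytest.raises(ValueError, match="unknown taxa"):
            phylo.is_monophyletic(phy, {"ZZZ"})


def test_newick_round_trip_preserves_topology_lengths_and_supports(tmp_path):
    fam, _ = _two_clade_family()
    phy = phylo.bootstrap_support(fam, n_reps=10, seed=10)
    out = tmp_path / "t.nwk"
    phy.write_newick(out)
    back = phylo.read_newick(out)
    assert phylo.edge_bipartitions(back) == phylo.edge_bipartitions(phy.tree)
    orig = {leaf.name: leaf.length for leaf in phy.tree.tips()}
    rt = {leaf.name: leaf.length for leaf in back.tips()}
    assert all(abs(orig[k] - rt[k]) < 1e-9 for k in orig)
    # supports survive as internal node labels
    labels = {n.name for n in back.non_tips() if n.name is not None}
    assert labels >= {f"{v:g}" for v in phy.supports.values() if v > 0}
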