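"""Tree container and combinatorial algebra."""

import itertools

import numpy as np
import pytest

from chloroscape.trees import (
    Bipartition,
    NewickError,
    bipartitions,
    internal_edges,
    midpoint_root,
    nni_neighbors,
    parse_newick,
    quartet_agreement,
    rf_distance,
    root_to_tip_depths,
    ultrametricize,
    write_newick,
)

from conftest import random_binary_tree


class TestNewick:
    def test_basic_parse(self):
        t = parse_newick("(A,B,(C,D));")
        assert t.tip_labels() == {"A", "B", "C", "D"}
        assert len(bipartitions(t)) == 1

    def test_branch_lengths_attach_to_edges(self):
        t = parse_newick("((A:1,B:1):0.5,C:1.5);")
        lengths = {n.label: n.length for n in t.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 1.5}
        internal = [n for n in t.postorder() if not n.is_tip and n.parent]
        assert internal[0].length == 0.5

    @pytest.mark.parametrize(
        "bad",
        ["(A,(B;", "(A,B));", "(A,A,B);", "(A,,B);", "(A,B)", "((A,B,);"],
    )
    def test_parse_errors(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_parse_error_names_duplicate_label(self):
        with pytest.raises(NewickError, match="duplicate tip label 'X'"):
            parse_newick("(X,(X,Y),Z);")

    def test_default_branch_length(self):
        t = parse_newick("(A,B,(C,D));", default_branch_length=2.5)
        assert all(n.length == 2.5 for n in t.tips())

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = random_binary_tree([f"t{i}" for i in range(8)], rng)
            back = parse_newick(write_newick(t))
            assert rf_distance(t, back) == 0
            d1 = root_to_tip_depths(midpoint_root(t))
            d2 = root_to_tip_depths(midpoint_root(back))
            for k in d1:
                assert d1[k] == pytest.approx(d2[k], abs=1e-12)

    def test_round_trip_against_dendropy(self):
        import dendropy

        rng = np.random.default_rng(1)
        t = random_binary_tree([f"t{i}" for i in range(10)], rng)
        dt = dendropy.Tree.get(data=write_newick(t), schema="newick")
        assert {leaf.taxon.label for leaf in dt.leaf_node_iter()} == t.tip_labels()


class TestBipartitions:
    def test_four_tip_resolved(self):
        t = parse_newick("((A,B),(C,D));")
        assert bipartitions(t) == {Bipartition(["A", "B"], ["C", "D"])}

    def test_star_has_none(self):
        assert bipartitions(parse_newick("(A,B,C,D);")) == set()

    def test_caterpillar_enumeration(self):
        # unrooted (((A,B),C),D,E): internal edges separate AB and ABC
        t = parse_newick("(((A,B),C),D,E);")
        assert bipartitions(t) == {
            Bipartition(["A", "B"], ["C", "D", "E"]),
            Bipartition(["A", "B", "C"], ["D", "E"]),
        }

    def test_binary_count_is_n_minus_3(self):
        rng = np.random.default_rng(2)
        for n in (4, 6, 9):
            t = random_binary_tree([f"t{i}" for i in range(n)], rng)
            assert len(bipartitions(t)) == n - 3

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            bipartitions(parse_newick("(A,B,C);"))


def _rf_oracle(t1, t2):
    """Independent check: dendropy symmetric difference."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestRFDistance:
    def test_identical_zero(self):
        t = parse_newick("((A,B),(C,D),E);")
        assert rf_distance(t, t) == 0

    def test_conflicting_quartets(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 2
        assert rf_distance(t1, t2, normalized=True) == 1.0

    def test_tip_mismatch_reports_labels(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        with pytest.raises(ValueError, match="E"):
            rf_distance(t1, t2)

    def test_matches_dendropy_on_random_pairs(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(30):
            t1 = random_binary_tree(labels, rng)
            t2 = random_binary_tree(labels, rng)
            assert rf_distance(t1, t2) == _rf_oracle(t1, t2)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(4)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(100):
            a, b, c = (random_binary_tree(labels, rng) for _ in range(3))
            dab, dbc, dac = rf_distance(a, b), rf_distance(b, c), rf_distance(a, c)
            assert dab == rf_distance(b, a)
            assert rf_distance(a, a) == 0
            assert dac <= dab + dbc


def _quartet_oracle(t1, t2):
    """Brute force: prune both trees to every 4-subset and compare the
    induced splits (independent of the distance-based production path)."""
    common = sorted(t1.tip_labels() & t2.tip_labels())
    shared = comparable = 0
    for quad in itertools.combinations(common, 4):
        s1 = bipartitions_or_none(t1.prune_to(quad))
        s2 = bipartitions_or_none(t2.prune_to(quad))
        if s1 is not None and s2 is not None:
            comparable += 1
            if s1 == s2:
                shared += 1
    return shared, comparable


def bipartitions_or_none(four_tip_tree):
    bips = bipartitions(four_tip_tree)
    return next(iter(bips)) if bips else None


class TestQuartets:
    def test_identical_five_tip(self):
        t = parse_newick("(((A,B),C),D,E);")
        assert quartet_agreement(t, t) == (5, 5)

    def test_conflicting_four_tip(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert quartet_agreement(t1, t2) == (0, 1)

    def test_star_has_no_comparable(self):
        t1 = parse_newick("((A,B),(C,D));")
        star = parse_newick("(A,B,C,D);")
        assert quartet_agreement(t1, star) == (0, 0)

    def test_too_few_shared(self):
        with pytest.raises(ValueError):
            quartet_agreement(parse_newick("(A,B,C);"), parse_newick("(A,B,C);"))

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(7)]
        for _ in range(20):
            t1 = random_binary_tree(labels, rng)
            t2 = random_binary_tree(labels, rng)
            assert quartet_agreement(t1, t2) == _quartet_oracle(t1, t2)

    def test_partial_taxon_overlap(self):
        t1 = parse_newick("(((A,B),C),(D,E));")
        t2 = parse_newick("(((A,B),C),(D,F));")
        # shared taxa are {A,B,C,D}: one quartet, resolved identically
        assert quartet_agreement(t1, t2) == (1, 1)


class TestExhaustiveFiveTip:
    def test_rf_and_quartets_match_oracles_on_all_pairs(self, five_tip_topologies):
        trees = five_tip_topologies
        assert len(trees) == 15
        for t1, t2 in itertools.combinations(trees, 2):
            b1, b2 = bipartitions(t1), bipartitions(t2)
            assert rf_distance(t1, t2) == len(b1 ^ b2)
            assert quartet_agreement(t1, t2) == _quartet_oracle(t1, t2)


class TestNNI:
    def test_central_edge_four_tips(self):
        t = parse_newick("((A,B),(C,D));")
        n1, n2 = nni_neighbors(t, Bipartition(["A", "B"], ["C", "D"]))
        got = {frozenset(map(repr, bipartitions(n))) for n in (n1, n2)}
        assert got == {
            frozenset({repr(Bipartition(["A", "C"], ["B", "D"]))}),
            frozenset({repr(Bipartition(["A", "D"], ["B", "C"]))}),
        }
        assert rf_distance(t, n1) == 2
        assert rf_distance(t, n2) == 2

    def test_neighbor_count_is_2n_minus_6(self):
        rng = np.random.default_rng(6)
        t = random_binary_tree([f"t{i}" for i in range(6)], rng)
        neighbors = []
        for edge in internal_edges(t):
            neighbors.extend(nni_neighbors(t, edge))
        assert len(neighbors) == 6
        reprs = {frozenset(map(repr, bipartitions(n))) for n in neighbors}
        assert len(reprs) == 6  # all distinct
        assert all(rf_distance(t, n) == 2 for n in neighbors)

    def test_pendant_edge_rejected(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(ValueError, match="pendant"):
            nni_neighbors(t, (["A"], ["B", "C", "D"]))


class TestUltrametricize:
    def test_already_ultrametric_unchanged(self):
        t = parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        u = ultrametricize(t)
        depths = root_to_tip_depths(u)
        assert all(abs(d - 1.0) < 1e-9 for d in depths.values())
        assert rf_distance(t, u) == 0
        # relative node heights preserved (already clock-like): C-D split at 0.75
        for node in u.postorder():
            if not node.is_tip and node.parent is not None:
                kids = {c.label for c in node.children}
                if kids == {"C", "D"}:
                    assert node.children[0].length == pytest.approx(0.75)

    def test_depth_variance_zero(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = random_binary_tree([f"t{i}" for i in range(9)], rng)
            u = ultrametricize(t)
            depths = np.array(list(root_to_tip_depths(u).values()))
            assert depths.std() < 1e-9
            assert depths.max() == pytest.approx(1.0, abs=1e-9)
            assert rf_distance(t, u) == 0

    def test_parent_child_age_clamping(self):
        # B's long pendant edge pushes its parent's mean path above the root's
        t = parse_newick("(((A:0.1,B:10):0.1,C:0.1):0.1,D:0.1);")
        u = ultrametricize(t)
        for node in u.preorder():
            if node.parent is not None:
                assert node.length >= 0

    def test_zero_height_rejected(self):
        t = parse_newick("((A:0,B:0):0,C:0);")
        with pytest.raises(ValueError):
            ultrametricize(t)
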