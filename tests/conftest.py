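import pytest

from chloroscape.trees import Node, Tree, parse_newick


def attach_tip(tree: Tree, node_index: int, label: str) -> Tree:
    """Insert a new tip by splitting the edge above the node_index-th
    non-root node (preorder)."""
    t = tree.copy()
    candidates = [n for n in t.preorder() if n.parent is not None]
    target = candidates[node_index]
    parent = target.parent
    mid = Node()
    idx = parent.children.index(target)
    parent.children[idx] = mid
    mid.parent = parent
    mid.length = 1.0
    target.parent = None
    mid.add_child(target)
    mid.add_child(Node(label, 1.0))
    return t


def enumerate_unrooted(labels) -> list[Tree]:
    """All distinct unrooted binary topologies on the given labels,
    constructed by successive tip insertion (1, 3, 15, 105, ... trees)."""
    labels = list(labels)
    base = parse_newick(f"({labels[0]},{labels[1]},{labels[2]});")
    trees = [base]
    for label in labels[3:]:
        nxt = []
        for t in trees:
            n_edges = sum(1 for n in t.preorder() if n.parent is not None)
            for e in range(n_edges):
                nxt.append(attach_tip(t, e, label))
        trees = nxt
    return trees


def random_binary_tree(labels, rng, min_len=0.1, max_len=1.0) -> Tree:
    """Random unrooted binary tree with uniform random branch lengths."""
    labels = list(labels)
    t = parse_newick(f"({labels[0]},{labels[1]},{labels[2]});")
    for label in labels[3:]:
        n_edges = sum(1 for n in t.preorder() if n.parent is not None)
        t = attach_tip(t, int(rng.integers(n_edges)), label)
    for node in t.preorder():
        if node.parent is not None:
            node.length = float(rng.uniform(min_len, max_len))
    return t


@pytest.fixture(scope="session")
def five_tip_topologies():
    return enumerate_unrooted(["A", "B", "C", "D", "E"])


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced benchmark dataset shared by integration tests."""
    from chloroscape.simulate import BenchmarkConfig, make_benchmark_dataset

    cfg = BenchmarkConfig(n_taxa=10, n_genes=20)
    return make_benchmark_dataset(cfg, seed=7)
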