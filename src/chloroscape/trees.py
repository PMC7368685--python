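"""Phylogenetic tree container and combinatorial tree algebra.

Provides a lightweight rooted/unrooted tree with Newick I/O and the
operations the rest of the package builds on: bipartition extraction,
Robinson-Foulds distances, quartet agreement, nearest-neighbour
interchange, midpoint rooting and relative-time ultrametricization.

Branch lengths are non-negative reals whose unit depends on context:
expected substitutions per site for inferred trees, coalescent units for
species trees driving the multispecies coalescent, or relative time for
clock trees.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Node",
    "Tree",
    "Bipartition",
    "NewickError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "rf_distance",
    "quartet_agreement",
    "quartet_resolutions",
    "internal_edges",
    "nni_neighbors",
    "midpoint_root",
    "ultrametricize",
    "topological_distance_matrix",
]


class NewickError(ValueError):
    """Raised for malformed Newick input; message carries position/label."""


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, node: "Node") -> None:
        node.parent = self
        self.children.append(node)

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        node.parent = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label!r} len={self.length}>"


class Tree:
    """A labelled tree. ``rooted`` means the root is a degree-2 node."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.tips())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def rooted(self) -> bool:
        return len(self.root.children) == 2

    # -- copying / restructuring ------------------------------------------
    def copy(self) -> "Tree":
        def _cp(node: Node) -> Node:
            new = Node(node.label, node.length)
            for c in node.children:
                new.add_child(_cp(c))
            return new

        return Tree(_cp(self.root))

    def unroot(self) -> "Tree":
        """Suppress a degree-2 root in place (no-op if already unrooted)."""
        root = self.root
        if len(root.children) != 2:
            return self
        a, b = root.children
        keep, move = (a, b) if not a.is_tip else (b, a)
        if keep.is_tip:  # 2-tip tree cannot be unrooted
            return self
        la = keep.length or 0.0
        lb = move.length or 0.0
        root.remove_child(keep)
        root.remove_child(move)
        move.length = la + lb
        keep.add_child(move)
        keep.length = None
        keep.parent = None
        self.root = keep
        return self

    def reroot_at(self, node: Node) -> "Tree":
        """Make ``node`` (a node of this tree) the traversal root in place."""
        if node is self.root:
            return self
        path = []
        cur = node
        while cur is not None:
            path.append(cur)
            cur = cur.parent
        # reverse parent/child relationships along root->node path
        for child, parent in zip(reversed(path[:-1]), reversed(path[1:])):
            parent.remove_child(child)
            child.add_child(parent)
            parent.length = child.length
        node.length = None
        node.parent = None
        self.root = node
        return self

    def prune_to(self, taxa: Iterable[str]) -> "Tree":
        """Return a copy restricted to ``taxa`` with unary nodes suppressed."""
        keep = set(taxa)
        t = self.copy()
        changed = True
        while changed:
            changed = False
            for node in list(t.postorder()):
                if node.is_tip and node.label not in keep and node.parent is not None:
                    node.parent.remove_child(node)
                    changed = True
        # suppress unary internal nodes
        for node in list(t.postorder()):
            if node.parent is not None and len(node.children) == 1:
                child = node.children[0]
                node.remove_child(child)
                child.length = (child.length or 0.0) + (node.length or 0.0)
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
        while len(t.root.children) == 1:
            new_root = t.root.children[0]
            new_root.parent = None
            new_root.length = None
            t.root = new_root
        return t

    # -- I/O ---------------------------------------------------------------
    def to_newick(self, lengths: bool = True) -> str:
        return write_newick(self, lengths=lengths)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {self.n_tips} tips>"


# ---------------------------------------------------------------------------
# Newick parsing / writing


def parse_newick(text: str, default_branch_length: float = 1.0) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Absent branch lengths default to ``default_branch_length`` on non-root
    edges (coalescent-unit trees are sometimes distributed topology-only).
    Quoting is not supported; labels must not contain ``(),:;``.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("Newick statement must end with ';'")
    s = s[:-1]
    pos = 0
    specials = "(),:;"

    def err(msg: str) -> NewickError:
        return NewickError(f"{msg} at position {pos}")

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in specials and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def parse_length() -> float | None:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos] in "+-eE." or s[pos].isdigit()):
                pos += 1
            try:
                val = float(s[start:pos])
            except ValueError:
                raise err(f"invalid branch length {s[start:pos]!r}")
            if val < 0:
                raise err("negative branch length")
            return val
        return None

    def parse_subtree() -> Node:
        nonlocal pos
        while pos < len(s) and s[pos].isspace():
            pos += 1
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node = Node()
            node.add_child(parse_subtree())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.add_child(parse_subtree())
            if pos >= len(s) or s[pos] != ")":
                raise err("unbalanced parentheses: expected ')'")
            pos += 1
            lbl = parse_label()
            node.label = lbl or None  # internal label (e.g. support); ignored
            node.length = parse_length()
            return node
        lbl = parse_label()
        if not lbl:
            raise err("empty tip label")
        node = Node(lbl)
        node.length = parse_length()
        return node

    root = parse_subtree()
    while pos < len(s) and s[pos].isspace():
        pos += 1
    if pos != len(s):
        raise NewickError(f"trailing characters at position {pos}: {s[pos:]!r}")
    tree = Tree(root)
    labels = [n.label for n in tree.tips()]
    seen: set[str] = set()
    for lbl in labels:
        if lbl in seen:
            raise NewickError(f"duplicate tip label {lbl!r}")
        seen.add(lbl)
    for node in tree.preorder():
        if node is not tree.root and node.length is None:
            node.length = default_branch_length
    if tree.root.is_tip:
        raise NewickError("tree must have at least 2 tips")
    return tree


def _fmt_len(x: float) -> str:
    # repr-style shortest round-trip representation keeps lengths exact
    return repr(float(x))


def write_newick(tree: Tree, lengths: bool = True) -> str:
    def _w(node: Node, top: bool) -> str:
        if node.is_tip:
            core = node.label or ""
        else:
            core = "(" + ",".join(_w(c, False) for c in node.children) + ")"
            if node.label and not top:
                core += node.label
        if lengths and not top and node.length is not None:
            core += ":" + _fmt_len(node.length)
        return core

    return _w(tree.root, True) + ";"


def read_newick_file(path) -> list[Tree]:
    """Read a multi-tree Newick file: one statement per line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(path, trees: Sequence[Tree]) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Bipartitions and Robinson-Foulds


class Bipartition:
    """A non-trivial split of the tip set induced by one internal edge.

    Canonical orientation: the lexicographically smaller side is stored
    first so equality and hashing are orientation-independent.
    """

    __slots__ = ("side1", "side2")

    def __init__(self, a: Iterable[str], b: Iterable[str]):
        fa, fb = frozenset(a), frozenset(b)
        if len(fa) < 2 or len(fb) < 2:
            raise ValueError("both sides of a bipartition need >= 2 tips")
        if fa & fb:
            raise ValueError("bipartition sides overlap")
        if tuple(sorted(fa)) > tuple(sorted(fb)):
            fa, fb = fb, fa
        self.side1, self.side2 = fa, fb

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Bipartition)
            and self.side1 == other.side1
            and self.side2 == other.side2
        )

    def __hash__(self) -> int:
        return hash((self.side1, self.side2))

    def __repr__(self) -> str:
        return (
            "|".join(
                ",".join(sorted(side)) for side in (self.side1, self.side2)
            )
        )


def bipartitions(tree: Tree) -> set[Bipartition]:
    """Non-trivial bipartitions of the unrooted form of ``tree``.

    A binary n-tip tree yields exactly n - 3; multifurcations yield fewer.
    """
    if tree.n_tips < 4:
        raise ValueError("bipartitions require a tree with >= 4 tips")
    t = tree.copy().unroot()
    all_tips = t.tip_labels()
    below: dict[int, frozenset[str]] = {}
    out: set[Bipartition] = set()
    for node in t.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node.parent is not None:
                side = below[id(node)]
                other = all_tips - side
                if len(side) >= 2 and len(other) >= 2:
                    out.add(Bipartition(side, other))
    return out


def _check_same_tips(t1: Tree, t2: Tree) -> frozenset[str]:
    l1, l2 = t1.tip_labels(), t2.tip_labels()
    if l1 != l2:
        only1 = sorted(l1 - l2)
        only2 = sorted(l2 - l1)
        raise ValueError(
            f"tip sets differ: only in first {only1}, only in second {only2}"
        )
    return l1


def rf_distance(t1: Tree, t2: Tree, normalized: bool = False) -> float:
    """Robinson-Foulds distance: symmetric difference of bipartition sets.

    Computed on unrooted forms. The normalized variant divides by
    2(n - 3), the maximum for binary trees.
    """
    labels = _check_same_tips(t1, t2)
    b1, b2 = bipartitions(t1), bipartitions(t2)
    d = len(b1 ^ b2)
    if normalized:
        denom = 2 * (len(labels) - 3)
        return d / denom if denom > 0 else 0.0
    return float(d)


# ---------------------------------------------------------------------------
# Quartets


def topological_distance_matrix(tree: Tree, order: Sequence[str]) -> np.ndarray:
    """Pairwise path lengths in edge counts between the listed tips."""
    # adjacency over all nodes
    nodes = list(tree.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for n in nodes:
        if n.parent is not None:
            i, j = index[id(n)], index[id(n.parent)]
            adj[i].append(j)
            adj[j].append(i)
    tip_idx = {n.label: index[id(n)] for n in nodes if n.is_tip}
    missing = [lbl for lbl in order if lbl not in tip_idx]
    if missing:
        raise ValueError(f"labels not in tree: {missing}")
    D = np.zeros((len(order), len(order)), dtype=np.int32)
    for a, lbl in enumerate(order):
        src = tip_idx[lbl]
        dist = np.full(len(nodes), -1, dtype=np.int32)
        dist[src] = 0
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for b, lbl2 in enumerate(order):
            D[a, b] = dist[tip_idx[lbl2]]
    return D


def quartet_resolutions(
    tree: Tree, order: Sequence[str], quartets: np.ndarray
) -> np.ndarray:
    """Resolution code per quartet of tips (indices into ``order``).

    Codes: 0 = ab|cd, 1 = ac|bd, 2 = ad|bc, -1 = unresolved. Uses the
    four-point condition on topological distances, which is intrinsic to
    the induced subtree, so no explicit restriction is needed.
    """
    D = topological_distance_matrix(tree, order)
    a, b, c, d = (quartets[:, k] for k in range(4))
    sums = np.stack(
        [D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c]], axis=1
    )
    code = np.argmin(sums, axis=1).astype(np.int8)
    smallest = np.take_along_axis(sums, code[:, None].astype(np.int64), axis=1)[:, 0]
    ties = (sums == smallest[:, None]).sum(axis=1) > 1
    code[ties] = -1
    return code


def _quartet_index(n: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), 4)), dtype=np.int64)


def quartet_agreement(t1: Tree, t2: Tree) -> tuple[int, int]:
    """(shared, comparable) quartet counts on the shared-tip restriction.

    ``comparable`` counts 4-tip subsets resolved in both trees; ``shared``
    those resolved identically.
    """
    common = sorted(t1.tip_labels() & t2.tip_labels())
    if len(common) < 4:
        raise ValueError("quartet agreement requires >= 4 shared tips")
    quartets = _quartet_index(len(common))
    r1 = quartet_resolutions(t1, common, quartets)
    r2 = quartet_resolutions(t2, common, quartets)
    both = (r1 >= 0) & (r2 >= 0)
    return int(((r1 == r2) & both).sum()), int(both.sum())


# ---------------------------------------------------------------------------
# NNI


def internal_edges(tree: Tree) -> list[Bipartition]:
    """Internal edges of the unrooted form, identified by their splits."""
    return sorted(bipartitions(tree), key=repr)


def _as_bipartition(edge) -> Bipartition:
    if isinstance(edge, Bipartition):
        return edge
    try:
        a, b = edge
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot interpret edge spec {edge!r}") from exc
    if len(tuple(a)) < 2 or len(tuple(b)) < 2:
        raise ValueError("pendant edge: NNI requires an internal edge")
    return Bipartition(a, b)


def nni_neighbors(tree: Tree, edge) -> tuple[Tree, Tree]:
    """The two alternative resolutions around an internal edge.

    ``edge`` is a :class:`Bipartition` (or a pair of label collections).
    Both neighbours differ from ``tree`` by RF distance 2 at that edge.
    """
    bip = _as_bipartition(edge)
    base = tree.copy().unroot()
    if bip not in bipartitions(base):
        raise ValueError(f"edge {bip!r} is not an internal edge of the tree")

    def build(swap_to: int) -> Tree:
        t = base.copy()
        below: dict[int, frozenset[str]] = {}
        target = None
        for node in t.postorder():
            if node.is_tip:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node.parent is not None and below[id(node)] in (bip.side1, bip.side2):
                target = node
        assert target is not None
        parent = target.parent
        t.reroot_at(parent)
        others = [c for c in parent.children if c is not target]
        if len(others) != 2 or len(target.children) != 2:
            raise ValueError("NNI requires a binary neighbourhood around the edge")
        x = target.children[0]
        y = others[swap_to]
        target.remove_child(x)
        parent.remove_child(y)
        target.add_child(y)
        parent.add_child(x)
        return t

    return build(0), build(1)


# ---------------------------------------------------------------------------
# Rooting and ultrametricization


def midpoint_root(tree: Tree) -> Tree:
    """Root a copy of ``tree`` at the midpoint of the longest tip-tip path."""
    t = tree.copy()
    if t.rooted:
        t.unroot()
    tips = t.tips()
    # path lengths between tips via per-tip depth from a DFS rooted anywhere
    best = (-1.0, None, None)
    depths: dict[int, dict[int, float]] = {}

    nodes = list(t.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(nodes))}
    for n in nodes:
        if n.parent is not None:
            i, j = index[id(n)], index[id(n.parent)]
            w = n.length or 0.0
            adj[i].append((j, w))
            adj[j].append((i, w))
    tip_ids = [index[id(n)] for n in tips]

    def dists_from(src: int) -> np.ndarray:
        dist = np.full(len(nodes), np.nan)
        dist[src] = 0.0
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if math.isnan(dist[v]):
                    dist[v] = dist[u] + w
                    stack.append(v)
        return dist

    for i in tip_ids:
        dist = dists_from(i)
        for j in tip_ids:
            if dist[j] > best[0]:
                best = (dist[j], i, j)
    total, src, dst = best
    if total <= 0:
        # zero-length tree: root arbitrarily between root's first child
        child = t.root.children[0]
        new_root = Node()
        t.root.remove_child(child)
        new_root.add_child(child)
        new_root.add_child(t.root)
        t.root.length = 0.0
        t.root = new_root
        new_root.parent = None
        return t
    # walk the src -> dst path accumulating lengths until the midpoint
    parent_of = {src: None}
    stack = [src]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in parent_of:
                parent_of[v] = (u, w)
                stack.append(v)
    path = []
    cur = dst
    while cur is not None:
        entry = parent_of[cur]
        if entry is None:
            path.append((cur, 0.0))
            break
        path.append((cur, entry[1]))
        cur = entry[0]
    path.reverse()  # starts at src
    half = total / 2.0
    acc = 0.0
    for (node_i, _), (next_i, next_w) in zip(path[:-1], path[1:]):
        if acc + next_w >= half - 1e-15:
            # midpoint lies on edge node_i -- next_i, offset from node_i
            a = nodes[node_i]
            b = nodes[next_i]
            offset = half - acc
            t.reroot_at(a)  # b is now a child of a carrying the edge length
            assert b.parent is a
            w = b.length or 0.0
            a.remove_child(b)
            new_root = Node()
            new_root.add_child(b)
            b.length = max(w - offset, 0.0)
            new_root.add_child(a)
            a.length = offset
            t.root = new_root
            return t
        acc += next_w
    raise AssertionError("midpoint not located")  # pragma: no cover


def ultrametricize(tree: Tree, root_age: float = 1.0) -> Tree:
    """Mean-path-length smoothing to a relative-time clock tree.

    Each internal node's age is the mean path length to its descendant
    tips, clamped so a parent is never younger than a child, then scaled
    so the root age equals ``root_age``. Unrooted input is midpoint-rooted
    first. Topology is unchanged.
    """
    t = tree.copy() if tree.rooted else midpoint_root(tree)
    sums: dict[int, tuple[float, int]] = {}
    age: dict[int, float] = {}
    for node in t.postorder():
        if node.is_tip:
            sums[id(node)] = (0.0, 1)
            age[id(node)] = 0.0
        else:
            s = 0.0
            c = 0
            for ch in node.children:
                cs, cc = sums[id(ch)]
                s += cs + (ch.length or 0.0) * cc
                c += cc
            sums[id(node)] = (s, c)
            mean_path = s / c
            age[id(node)] = max(
                mean_path, max(age[id(ch)] for ch in node.children)
            )
    root_depth = age[id(t.root)]
    if root_depth <= 0:
        raise ValueError("cannot ultrametricize a zero-height tree")
    scale = root_age / root_depth
    for node in t.postorder():
        if node.parent is not None:
            node.length = (age[id(node.parent)] - age[id(node)]) * scale
    return t


def root_to_tip_depths(tree: Tree) -> dict[str, float]:
    depth: dict[int, float] = {id(tree.root): 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
        if node.is_tip:
            out[node.label] = depth[id(node)]
    return out
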