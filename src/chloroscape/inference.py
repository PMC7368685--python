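"""Distance-based gene-tree estimation: JC69 distances + neighbor joining.

A deliberately simple, deterministic stand-in for external ML tree
inference so synthetic end-to-end runs are self-contained. Pairwise
comparisons use pairwise deletion (columns where both sequences carry an
unambiguous base); saturated pairs (p >= 3/4) are capped at ``d_max``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .alignment import GeneAlignment
from .trees import Node, Tree

log = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "jc_distance_matrix", "neighbor_joining"]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(v, v.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("matrix diagonal not zero")
        if not np.isfinite(v).all():
            raise ValueError("matrix entries must be finite")
        if (v < 0).any():
            raise ValueError("matrix entries must be non-negative")
        self.values = v

    def to_phylip(self) -> str:
        lines = [str(len(self.labels))]
        for lbl, row in zip(self.labels, self.values):
            lines.append(lbl + "  " + "  ".join(f"{x:.8f}" for x in row))
        return "\n".join(lines) + "\n"


def jc_distance_matrix(aln: GeneAlignment, d_max: float = 5.0) -> DistanceMatrix:
    """Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p) with pairwise
    deletion; p >= 3/4 is capped at ``d_max`` with a logged warning."""
    if aln.n_taxa < 2:
        raise ValueError(f"{aln.name}: need >= 2 sequences")
    M = aln.matrix()
    valid = np.isin(M, [b"A", b"C", b"G", b"T"])
    n = aln.n_taxa
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                raise ValueError(
                    f"{aln.name}: no comparable columns between "
                    f"{aln.taxa[i]} and {aln.taxa[j]}"
                )
            p = float((M[i, both] != M[j, both]).sum()) / total
            if p >= 0.75:
                log.warning(
                    "%s: saturated pair %s/%s (p=%.3f), capping at %.2f",
                    aln.name,
                    aln.taxa[i],
                    aln.taxa[j],
                    p,
                    d_max,
                )
                d = d_max
            else:
                d = min(-0.75 * math.log1p(-4.0 * p / 3.0), d_max)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(aln.taxa), D)


def neighbor_joining(dist: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-matrix minimization breaks ties at the lowest (row, column) index
    pair; negative branch-length estimates are clamped to zero. The
    output is unrooted (trifurcating root) for n >= 3.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    D = dist.values.copy()
    nodes: list[Node] = [Node(lbl) for lbl in dist.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) among minima for deterministic output
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((int(i), int(j)) for i, j in ties if i < j)
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        parent = Node()
        child_i, child_j = nodes[i_glob], nodes[j_glob]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent.add_child(child_i)
        parent.add_child(child_j)
        # distances from the new node to the others
        new_d = 0.5 * (sub[ai, :] + sub[aj, :] - dij)
        # reuse slot i_glob for the new node
        for k_local, k_glob in enumerate(active):
            D[i_glob, k_glob] = D[k_glob, i_glob] = max(new_d[k_local], 0.0)
        D[i_glob, i_glob] = 0.0
        nodes[i_glob] = parent
        active.remove(j_glob)

    # join the last three around a trifurcating root
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    root = Node()
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.add_child(nodes[idx])
    return Tree(root)
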