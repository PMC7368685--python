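"""Robinson-Foulds tree space: distance matrix, PCoA ordination, and the
gene-tree discordance (GD) statistic.

GD for a gene is the Euclidean distance between its gene tree and the
coalescent species tree in the first two axes of a classical PCoA of the
pairwise RF distance matrix over {gene trees + species tree(s)}. A gene
tree topologically identical to the species tree has an identical RF row
and therefore GD = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .inference import DistanceMatrix
from .trees import Tree, bipartitions, rf_distance

log = logging.getLogger(__name__)

__all__ = [
    "restrict_to_common_taxa",
    "rf_matrix",
    "pcoa",
    "Ordination",
    "gene_discordance",
    "DiscordanceTable",
]


def restrict_to_common_taxa(
    trees: dict[str, Tree] | list[Tree], min_tips: int = 4
) -> tuple[dict[str, Tree] | list[Tree], dict]:
    """Prune every tree to the intersection of all tip sets.

    Trees whose pruned form has fewer than ``min_tips`` tips are dropped.
    Returns the pruned collection plus a report of pruned taxa and
    dropped trees (mirrors removing incompletely sampled loci/taxa before
    tree-space analysis).
    """
    as_dict = isinstance(trees, dict)
    items = list(trees.items()) if as_dict else list(enumerate(trees))
    if len(items) < 2:
        raise ValueError("need >= 2 trees")
    # trees already below the usable size would only destroy the common
    # taxon set; drop them first (the heavily-incomplete-locus case)
    dropped = [key for key, t in items if t.n_tips < min_tips]
    items = [(key, t) for key, t in items if t.n_tips >= min_tips]
    if len(items) < 2:
        raise ValueError("fewer than 2 usable trees")
    common = frozenset.intersection(*(t.tip_labels() for _, t in items))
    if len(common) < 4:
        raise ValueError(
            f"only {len(common)} taxa shared by all trees; >= 4 required"
        )
    pruned = {}
    removed_taxa = sorted(
        set().union(*(t.tip_labels() for _, t in items)) - common
    )
    for key, t in items:
        pruned[key] = t.prune_to(common)
    report = {
        "common_taxa": sorted(common),
        "removed_taxa": removed_taxa,
        "dropped_trees": dropped,
    }
    if removed_taxa or dropped:
        log.info(
            "restrict_to_common_taxa: removed taxa %s; dropped trees %s",
            removed_taxa,
            dropped,
        )
    if as_dict:
        return pruned, report
    return [pruned[k] for k in sorted(pruned)], report


def rf_matrix(
    trees: dict[str, Tree] | list[Tree], normalized: bool = False
) -> DistanceMatrix:
    """Pairwise (unnormalized by default) RF distances; requires identical
    tip sets across all trees."""
    if isinstance(trees, dict):
        labels = list(trees)
        tlist = [trees[k] for k in labels]
    else:
        labels = [str(i) for i in range(len(trees))]
        tlist = list(trees)
    n = len(tlist)
    tips0 = tlist[0].tip_labels()
    for lbl, t in zip(labels, tlist):
        if t.tip_labels() != tips0:
            raise ValueError(
                f"tree {lbl} has a different tip set; run "
                "restrict_to_common_taxa first"
            )
    bips = [bipartitions(t) for t in tlist]
    D = np.zeros((n, n))
    denom = 2 * (len(tips0) - 3)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(len(bips[i] ^ bips[j]))
            if normalized and denom > 0:
                d /= denom
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D)


@dataclass
class Ordination:
    """Classical-MDS embedding of a distance matrix.

    Coordinates exist only for axes with positive eigenvalues; negative
    eigenvalues are reported (uncorrected) but excluded. Variance
    explained is relative to the sum of positive eigenvalues.
    """

    ids: list[str]
    coordinates: np.ndarray  # items x axes (positive-eigenvalue axes only)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    variance_explained: np.ndarray  # per retained axis, fraction

    def coords_of(self, item: str, n_axes: int = 2) -> np.ndarray:
        idx = self.ids.index(item)
        return self.coordinates[idx, :n_axes]


def pcoa(dist: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical multidimensional scaling (principal coordinate analysis).

    Eigendecomposes B = -1/2 J D^2 J. If fewer than ``k`` positive
    eigenvalues exist, all available axes are returned with a warning.
    Eigenvector signs follow a deterministic convention (largest-magnitude
    loading positive).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    D = dist.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = 0.5 * (B + B.T)
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(1e-10, 1e-10 * abs(w[0])) if n else 0.0
    pos = w > tol
    n_pos = int(pos.sum())
    if n_pos < k:
        log.warning("only %d positive eigenvalues; returning %d axes", n_pos, n_pos)
    n_axes = min(k, n_pos) if n_pos else 0
    coords = V[:, :n_pos] * np.sqrt(w[:n_pos])
    # deterministic sign convention
    for ax in range(coords.shape[1]):
        col = coords[:, ax]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, ax] = -col
    # items with identical distance rows coincide in the embedding; make
    # that exact (identity of indiscernibles survives floating point)
    seen: dict[bytes, int] = {}
    for i in range(n):
        key = D[i].tobytes()
        if key in seen:
            coords[i] = coords[seen[key]]
        else:
            seen[key] = i
    var = w[:n_pos] / w[:n_pos].sum() if n_pos else np.array([])
    return Ordination(
        ids=list(dist.labels),
        coordinates=coords,
        eigenvalues=w,
        variance_explained=var,
    )


@dataclass
class DiscordanceTable:
    """Per-gene discordance (GD) relative to the coalescent species tree."""

    gd: dict[str, float]
    species_tree_id: str
    mean: float = field(init=False)
    median: float = field(init=False)

    def __post_init__(self) -> None:
        vals = np.array(list(self.gd.values()))
        self.mean = float(vals.mean()) if vals.size else float("nan")
        self.median = float(np.median(vals)) if vals.size else float("nan")

    def to_tsv(self) -> str:
        lines = ["gene\tGD"]
        for gene in sorted(self.gd):
            lines.append(f"{gene}\t{self.gd[gene]:.10g}")
        return "\n".join(lines) + "\n"


def gene_discordance(
    ordination: Ordination,
    species_tree_id: str,
    exclude: tuple[str, ...] | list[str] = (),
) -> DiscordanceTable:
    """GD per gene: Euclidean distance to ``species_tree_id`` in axes 1-2.

    ``exclude`` lists further non-gene items (e.g. a second species tree)
    to leave out of the per-gene table.
    """
    if species_tree_id not in ordination.ids:
        raise ValueError(f"unknown id {species_tree_id!r} in ordination")
    if ordination.coordinates.shape[1] < 1:
        # fully degenerate tree space (all trees identical): every item
        # coincides, so every distance is zero
        gd = {
            item: 0.0
            for item in ordination.ids
            if item not in set(exclude) | {species_tree_id}
        }
        return DiscordanceTable(gd=gd, species_tree_id=species_tree_id)
    n_axes = min(2, ordination.coordinates.shape[1])
    ref = ordination.coords_of(species_tree_id, n_axes)
    skip = set(exclude) | {species_tree_id}
    gd = {}
    for item in ordination.ids:
        if item in skip:
            continue
        delta = ordination.coords_of(item, n_axes) - ref
        gd[item] = float(np.sqrt((delta**2).sum()))
    return DiscordanceTable(gd=gd, species_tree_id=species_tree_id)
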