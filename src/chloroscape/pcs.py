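"""Partitioned coalescence support (PCS) under the quartet criterion.

PCS quantifies each gene tree's positive or negative influence on the
clades of a summary-coalescent species tree. The optimality criterion is
the ASTRAL-style shared-quartet count: for each internal branch (clade)
of the species tree, the best alternative topology lacking that clade is
the candidate with the highest total quartet fit summed over genes, and a
gene's per-clade PCS is its fit difference between the species tree and
that alternative. Positive = support, negative = conflict, zero =
ambiguity. PCS depends on topology only, never on branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trees import (
    Bipartition,
    Tree,
    _quartet_index,
    bipartitions,
    internal_edges,
    nni_neighbors,
    quartet_resolutions,
)

__all__ = ["gene_quartet_fit", "pcs_scores", "PCSTable"]


def gene_quartet_fit(gene_tree: Tree, species_tree: Tree) -> int:
    """Shared resolved quartets between a gene tree and the species tree,
    restricted to their shared taxa."""
    from .trees import quartet_agreement

    shared, _ = quartet_agreement(gene_tree, species_tree)
    return shared


def _sign_class(x: int) -> str:
    return "positive" if x > 0 else ("negative" if x < 0 else "zero")


@dataclass
class PCSTable:
    """Gene-level PCS plus the per-clade decomposition."""

    pcs: dict[str, int]
    sign: dict[str, str]
    per_clade: dict[str, dict[str, int]]  # gene -> clade repr -> PCS
    clades: list[str]
    mode: str  # aggregation mode used ("sum over clades" or a focal clade)

    def to_tsv(self) -> str:
        lines = [f"# aggregation: {self.mode}", "gene\tPCS\tclass"]
        for gene in sorted(self.pcs):
            lines.append(f"{gene}\t{self.pcs[gene]}\t{self.sign[gene]}")
        return "\n".join(lines) + "\n"

    def per_clade_tsv(self) -> str:
        lines = ["gene\t" + "\t".join(self.clades)]
        for gene in sorted(self.per_clade):
            row = self.per_clade[gene]
            lines.append(
                gene + "\t" + "\t".join(str(row[c]) for c in self.clades)
            )
        return "\n".join(lines) + "\n"


class _FitCache:
    """Quartet-fit computations shared across candidate trees.

    Gene trees are compared with every candidate on the gene's shared-taxa
    quartet set; candidate resolutions are cached per (candidate, taxon
    set) because genes with complete sampling share them.
    """

    def __init__(self, species_taxa: frozenset[str]):
        self.species_taxa = species_taxa
        self._cand_cache: dict[tuple[int, tuple[str, ...]], np.ndarray] = {}
        self._quartet_cache: dict[int, np.ndarray] = {}

    def quartets(self, n: int) -> np.ndarray:
        if n not in self._quartet_cache:
            self._quartet_cache[n] = _quartet_index(n)
        return self._quartet_cache[n]

    def gene_resolutions(self, gene_tree: Tree) -> tuple[tuple[str, ...], np.ndarray]:
        taxa = tuple(sorted(gene_tree.tip_labels() & self.species_taxa))
        if len(taxa) < 4:
            raise ValueError("gene tree shares < 4 taxa with the species tree")
        return taxa, quartet_resolutions(gene_tree, taxa, self.quartets(len(taxa)))

    def candidate_resolutions(
        self, cand_id: int, cand_tree: Tree, taxa: tuple[str, ...]
    ) -> np.ndarray:
        key = (cand_id, taxa)
        if key not in self._cand_cache:
            self._cand_cache[key] = quartet_resolutions(
                cand_tree, taxa, self.quartets(len(taxa))
            )
        return self._cand_cache[key]


def pcs_scores(
    gene_trees: dict[str, Tree] | Sequence[Tree],
    species_tree: Tree,
    alternatives: str | Sequence[Tree] = "nni",
    focal_clade: Bipartition | None = None,
) -> PCSTable:
    """PCS for every gene against the species tree.

    ``alternatives`` is either ``"nni"`` (default: for each clade, the two
    nearest-neighbour-interchange resolutions around its branch) or an
    explicit list of alternative species trees (e.g. a concatenation ML
    tree); an explicit alternative challenges exactly the clades it lacks.
    ``focal_clade`` restricts the gene-level aggregation to one internal
    branch instead of summing over all of them.
    """
    if not isinstance(gene_trees, dict):
        gene_trees = {str(i): t for i, t in enumerate(gene_trees)}
    species_taxa = species_tree.tip_labels()
    clades = internal_edges(species_tree)
    if focal_clade is not None and focal_clade not in clades:
        raise ValueError("focal clade is not an internal edge of the species tree")

    # candidate set per clade
    per_clade_candidates: dict[Bipartition, list[int]] = {c: [] for c in clades}
    candidates: list[Tree] = []
    if isinstance(alternatives, str):
        if alternatives != "nni":
            raise ValueError(f"unknown alternatives mode {alternatives!r}")
        for c in clades:
            n1, n2 = nni_neighbors(species_tree, c)
            for alt in (n1, n2):
                per_clade_candidates[c].append(len(candidates))
                candidates.append(alt)
    else:
        for alt in alternatives:
            if alt.tip_labels() != species_taxa:
                raise ValueError(
                    "alternative species tree has a different taxon set"
                )
            alt_bips = bipartitions(alt)
            idx = len(candidates)
            candidates.append(alt)
            for c in clades:
                if c not in alt_bips:
                    per_clade_candidates[c].append(idx)

    cache = _FitCache(species_taxa)
    gene_res: dict[str, tuple[tuple[str, ...], np.ndarray]] = {
        g: cache.gene_resolutions(t) for g, t in gene_trees.items()
    }

    def fit(gene: str, cand_id: int, cand_tree: Tree) -> int:
        taxa, res_g = gene_res[gene]
        res_c = cache.candidate_resolutions(cand_id, cand_tree, taxa)
        return int(((res_g == res_c) & (res_g >= 0) & (res_c >= 0)).sum())

    # fit of every gene to the species tree itself (cand_id -1)
    species_fit = {g: fit(g, -1, species_tree) for g in gene_res}
    cand_fits: dict[int, dict[str, int]] = {}

    def cand_fit_all(cand_id: int) -> dict[str, int]:
        if cand_id not in cand_fits:
            cand_fits[cand_id] = {
                g: fit(g, cand_id, candidates[cand_id]) for g in gene_res
            }
        return cand_fits[cand_id]

    per_clade: dict[str, dict[str, int]] = {g: {} for g in gene_res}
    clade_names = [repr(c) for c in clades]
    for c, cname in zip(clades, clade_names):
        ids = per_clade_candidates[c]
        if not ids:
            for g in gene_res:
                per_clade[g][cname] = 0
            continue
        totals = [sum(cand_fit_all(i).values()) for i in ids]
        best = ids[int(np.argmax(totals))]
        best_fits = cand_fit_all(best)
        for g in gene_res:
            per_clade[g][cname] = species_fit[g] - best_fits[g]

    if focal_clade is not None:
        mode = f"focal clade {focal_clade!r}"
        pcs = {g: per_clade[g][repr(focal_clade)] for g in gene_res}
    else:
        mode = "sum over clades"
        pcs = {g: sum(per_clade[g].values()) for g in gene_res}
    sign = {g: _sign_class(v) for g, v in pcs.items()}
    return PCSTable(
        pcs=pcs, sign=sign, per_clade=per_clade, clades=clade_names, mode=mode
    )
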