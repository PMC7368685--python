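"""Synthetic plastome benchmark: species trees, multispecies-coalescent
gene trees, and nucleotide/codon alignments with planted heterogeneity.

The generator emulates the structure of a plastome phylogenomic data set:
~76 protein-coding genes of heterogeneous length, per-gene rate
multipliers with functional-group and region (LSC/SSC/IR) syndromes,
MSC-driven topological discordance among gene trees, purifying selection
(omega < 1) on all coding genes, clade-restricted loss of the ndh genes
and sporadic loss of a single small gene (rpl33-like). Every run is
reproducible bit-for-bit from (config, seed); the planted parameters are
returned as a :class:`SyntheticTruth` for recovery tests.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .alignment import GeneAlignment, write_fasta_alignment
from .rates import CODONS, GENETIC_CODE
from .trees import Node, Tree, write_newick_file

__all__ = [
    "simulate_species_tree",
    "simulate_msc_gene_trees",
    "simulate_nt_alignment",
    "simulate_codon_alignment",
    "inject_gene_loss",
    "make_benchmark_dataset",
    "BenchmarkConfig",
    "BenchmarkDataset",
    "SyntheticTruth",
    "hky_matrix",
    "gy94_matrix",
    "f3x4_frequencies",
    "derive_seed",
]

NT = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def derive_seed(seed: int, name: str) -> int:
    """Stage-specific sub-seed derived from a master seed by name hash."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Species tree (Yule)


def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0, seed: int = 0) -> Tree:
    """Ultrametric Yule tree with tips T1..Tn (branch lengths = time)."""
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    root = Node()
    active: list[tuple[Node, float]] = []  # (node, birth time)
    for _ in range(2):
        child = Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.length = t - born
        for _ in range(2):
            child = Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    labels = iter(f"T{i + 1}" for i in range(n_taxa))
    for node, born in active:
        node.label = next(labels)
        node.length = t - born
    return Tree(root)


def scale_tree(tree: Tree, factor: float) -> Tree:
    t = tree.copy()
    for node in t.preorder():
        if node.length is not None:
            node.length *= factor
    return t


def tree_height(tree: Tree) -> float:
    from .trees import root_to_tip_depths

    return max(root_to_tip_depths(tree).values())


# ---------------------------------------------------------------------------
# Multispecies coalescent


def simulate_msc_gene_trees(
    species_tree: Tree, n_genes: int, seed: int = 0
) -> list[Tree]:
    """Standard MSC with one haploid sample per species.

    Species-tree branch lengths are coalescent units; within a branch, k
    lineages coalesce at rate k(k-1)/2, and lineages reaching the root
    branch coalesce freely. Gene-tree branch lengths are coalescent units.
    """
    for node in species_tree.preorder():
        if node.parent is not None and (node.length is None or node.length <= 0):
            raise ValueError("species tree branch lengths must be positive")
    rng = np.random.default_rng(seed)
    # node ages (species tree must be read tips-up)
    depth: dict[int, float] = {id(species_tree.root): 0.0}
    for node in species_tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + node.length
    max_depth = max(depth[id(n)] for n in species_tree.tips())
    age = {k: max_depth - v for k, v in depth.items()}

    out: list[Tree] = []
    for _ in range(n_genes):
        lineages: dict[int, list[Node]] = {}
        gene_age: dict[int, float] = {}

        def coalesce_in(pool: list[Node], t0: float, t_end: float) -> list[Node]:
            t = t0
            pool = list(pool)
            while len(pool) > 1:
                k = len(pool)
                t_next = t + rng.exponential(2.0 / (k * (k - 1)))
                if t_next >= t_end:
                    return pool
                t = t_next
                i, j = sorted(rng.choice(k, size=2, replace=False))
                a = pool.pop(j)
                b = pool.pop(i)
                parent = Node()
                parent.add_child(a)
                parent.add_child(b)
                a.length = t - gene_age[id(a)]
                b.length = t - gene_age[id(b)]
                gene_age[id(parent)] = t
                pool.append(parent)
            return pool

        for node in species_tree.postorder():
            if node.is_tip:
                tip = Node(node.label)
                gene_age[id(tip)] = age[id(node)]
                pool = [tip]
            else:
                pool = []
                for c in node.children:
                    pool.extend(lineages[id(c)])
            if node.parent is None:
                pool = coalesce_in(pool, age[id(node)], math.inf)
            else:
                pool = coalesce_in(pool, age[id(node)], age[id(node.parent)])
            lineages[id(node)] = pool
        root = lineages[id(species_tree.root)][0]
        out.append(Tree(root))
    return out


# ---------------------------------------------------------------------------
# Substitution models


def _check_freqs(freqs: Sequence[float], n: int) -> np.ndarray:
    f = np.asarray(freqs, dtype=float)
    if f.shape != (n,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be non-negative and sum to 1")
    return f


def hky_matrix(kappa: float, base_freqs: Sequence[float]) -> np.ndarray:
    """HKY85 rate matrix (order ACGT), scaled to 1 substitution/site."""
    pi = _check_freqs(base_freqs, 4)
    Q = np.zeros((4, 4))
    for i, a in enumerate(NT):
        for j, b in enumerate(NT):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (a, b) in _TRANSITIONS else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate


def discrete_gamma_rates(shape: float, n_cat: int = 4) -> np.ndarray:
    """Equal-probability discrete gamma categories (median representatives),
    normalized to mean 1."""
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    q = (np.arange(n_cat) + 0.5) / n_cat
    rates = gamma_dist.ppf(q, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


def f3x4_frequencies(pos_freqs: Sequence[Sequence[float]]) -> np.ndarray:
    """F3x4 codon frequencies from position-specific base frequencies,
    renormalized over the 61 sense codons."""
    pf = [ _check_freqs(p, 4) for p in pos_freqs ]
    if len(pf) != 3:
        raise ValueError("need base frequencies for 3 codon positions")
    idx = {b: i for i, b in enumerate(NT)}
    freqs = np.array(
        [pf[0][idx[c[0]]] * pf[1][idx[c[1]]] * pf[2][idx[c[2]]] for c in CODONS]
    )
    return freqs / freqs.sum()


def gy94_matrix(
    kappa: float, omega: float, codon_freqs: Sequence[float]
) -> np.ndarray:
    """GY94 M0 codon rate matrix over the 61 sense codons.

    Single-nucleotide changes only; rate proportional to the target codon
    frequency, times kappa for transitions and omega for nonsynonymous
    changes. Scaled so one unit of branch length equals one expected
    nucleotide substitution per site (three per codon).
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    pi = _check_freqs(codon_freqs, 61)
    Q = np.zeros((61, 61))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            rate = pi[j]
            if diff[0] in _TRANSITIONS:
                rate *= kappa
            if GENETIC_CODE[ci] != GENETIC_CODE[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()  # codon substitutions per unit time
    return Q * (3.0 / mean_rate)  # branch lengths in nt substitutions/site


class _Propagator:
    """Transition probabilities P(t) = exp(Qt) via one eigendecomposition
    of the reversible generator (symmetrized form)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = Q * d[:, None] / d[None, :]
        S = 0.5 * (S + S.T)
        self.w, self.U = np.linalg.eigh(S)
        self.d = d

    def __call__(self, t: float) -> np.ndarray:
        M = (self.U * np.exp(self.w * t)) @ self.U.T
        P = M / self.d[:, None] * self.d[None, :]
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def _sample_children(P: np.ndarray, parent_states: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    u = rng.random(parent_states.shape[0])
    return (u[:, None] < cum[parent_states]).argmax(axis=1)


def _evolve_states(
    tree: Tree,
    propagator: _Propagator,
    root_freqs: np.ndarray,
    n_sites: int,
    rng,
    site_scale: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Sample leaf states down the tree; ``site_scale`` multiplies branch
    lengths per site (discrete-gamma heterogeneity)."""
    n_states = root_freqs.shape[0]
    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(n_states, size=n_sites, p=root_freqs)
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        if node.parent is None:
            continue
        t = node.length or 0.0
        parent = states[id(node.parent)]
        if site_scale is None:
            child = (
                parent.copy()
                if t == 0
                else _sample_children(propagator(t), parent, rng)
            )
        else:
            child = np.empty_like(parent)
            for cat in np.unique(site_scale):
                mask = site_scale == cat
                teff = t * float(cat)
                if teff == 0:
                    child[mask] = parent[mask]
                else:
                    child[mask] = _sample_children(
                        propagator(teff), parent[mask], rng
                    )
        states[id(node)] = child
        if node.is_tip:
            out[node.label] = child
    return out


def simulate_nt_alignment(
    gene_tree: Tree,
    length: int,
    kappa: float = 2.0,
    base_freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    gamma_shape: float | None = None,
    rate_multiplier: float = 1.0,
    seed: int = 0,
    name: str = "gene",
) -> GeneAlignment:
    """HKY(+discrete gamma) simulation on a tree with branch lengths in
    expected substitutions/site (before ``rate_multiplier``)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    pi = _check_freqs(base_freqs, 4)
    rng = np.random.default_rng(seed)
    Q = hky_matrix(kappa, pi) * rate_multiplier
    prop = _Propagator(Q, pi)
    site_scale = None
    if gamma_shape is not None:
        cats = discrete_gamma_rates(gamma_shape)
        site_scale = cats[rng.integers(len(cats), size=length)]
    leaves = _evolve_states(gene_tree, prop, pi, length, rng, site_scale)
    taxa = sorted(leaves)
    seqs = ["".join(NT[s] for s in leaves[t]) for t in taxa]
    return GeneAlignment(name, taxa, seqs, is_codon=False)


def simulate_codon_alignment(
    gene_tree: Tree,
    n_codons: int,
    kappa: float = 2.0,
    omega: float = 0.2,
    codon_freqs: Sequence[float] | None = None,
    seed: int = 0,
    rate_multiplier: float = 1.0,
    name: str = "gene",
) -> GeneAlignment:
    """GY94 M0 codon simulation (61 sense codons; no stops ever emitted).

    Branch lengths are expected nucleotide substitutions per site before
    ``rate_multiplier``.
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if codon_freqs is None:
        codon_freqs = f3x4_frequencies(DEFAULT_POSITION_FREQS)
    pi = _check_freqs(codon_freqs, 61)
    rng = np.random.default_rng(seed)
    Q = gy94_matrix(kappa, omega, pi) * rate_multiplier
    prop = _Propagator(Q, pi)
    leaves = _evolve_states(gene_tree, prop, pi, n_codons, rng, None)
    taxa = sorted(leaves)
    seqs = ["".join(CODONS[s] for s in leaves[t]) for t in taxa]
    return GeneAlignment(name, taxa, seqs, is_codon=True)


#: plastome-like AT-rich position-specific base frequencies (A, C, G, T)
DEFAULT_POSITION_FREQS = (
    (0.30, 0.18, 0.27, 0.25),
    (0.27, 0.22, 0.18, 0.33),
    (0.32, 0.15, 0.17, 0.36),
)


# ---------------------------------------------------------------------------
# Benchmark dataset


@dataclass
class GeneTruth:
    length: int
    rate_multiplier: float
    omega: float
    group: str
    region: str
    lost_taxa: set[str] = field(default_factory=set)
    usable: bool = True


@dataclass
class SyntheticTruth:
    """Planted parameters of a benchmark run, for recovery tests."""

    species_tree: Tree  # coalescent units
    genes: dict[str, GeneTruth]
    kappa: float
    position_freqs: tuple
    gamma_shape: float | None
    seed: int

    def to_tsv(self) -> str:
        lines = ["gene\tlength\trate_multiplier\tomega\tgroup\tregion\tlost_taxa\tusable"]
        for gene in sorted(self.genes):
            g = self.genes[gene]
            lines.append(
                f"{gene}\t{g.length}\t{g.rate_multiplier:.10g}\t{g.omega:.10g}\t"
                f"{g.group}\t{g.region}\t{','.join(sorted(g.lost_taxa))}\t{g.usable}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class BenchmarkDataset:
    species_tree: Tree  # coalescent units
    alignments: dict[str, GeneAlignment]
    gene_trees: dict[str, Tree]  # true MSC gene trees, coalescent units
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        aln_dir = os.path.join(outdir, "alignments")
        os.makedirs(aln_dir, exist_ok=True)
        for gene in sorted(self.alignments):
            write_fasta_alignment(
                os.path.join(aln_dir, f"{gene}.fasta"), self.alignments[gene]
            )
        with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
            fh.write(self.species_tree.to_newick() + "\n")
        names = sorted(self.gene_trees)
        write_newick_file(
            os.path.join(outdir, "gene_trees.nwk"),
            [self.gene_trees[g] for g in names],
        )
        with open(os.path.join(outdir, "gene_trees.ids"), "w") as fh:
            fh.write("\n".join(names) + "\n")
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write(self.truth.to_tsv())


@dataclass
class BenchmarkConfig:
    """Study conditions for the synthetic plastome benchmark.

    Defaults emulate a Gentianeae-like data set: 26 taxa, the 76-gene
    plastome template with its functional groups and LSC/SSC/IR regions,
    moderate incomplete lineage sorting, purifying selection on all genes
    with selection strength coupled to mutational lability (functional
    groups that mutate faster also tolerate more amino-acid change), a
    slower inverted repeat, clade-wide ndh loss and sporadic rpl33 loss.
    """

    n_taxa: int = 26
    n_genes: int = 76
    # A plastome is uniparentally inherited and effectively a single linked
    # locus, so deep coalescence is rare: long coalescent-unit branches give
    # mild MSC discordance, and most observed gene-tree scatter comes from
    # per-gene information content, as in real plastome data sets.
    tree_height_cu: float = 30.0  # species-tree height, coalescent units
    # calibrated so per-gene nucleotide diversity spans the range observed
    # in real plastome data sets (roughly 0.008-0.09 across genes)
    subs_per_cu: float = 0.0012  # nucleotide substitutions/site per CU
    kappa: float = 2.0
    gamma_shape: float | None = None  # codon genes: no extra site gamma
    rate_sigma: float = 0.5  # lognormal spread of per-gene multipliers
    group_base_rate: dict = field(
        default_factory=lambda: {
            "PSA": 0.55,
            "PSB": 0.55,
            "PET": 0.6,
            "ATP": 0.65,
            "Rubisco": 0.8,
            "NDH": 1.1,
            "RPL": 1.5,
            "RPS": 1.5,
            "RPO": 1.6,
            "OG": 1.8,
        }
    )
    region_multiplier: dict = field(
        default_factory=lambda: {"LSC": 1.0, "SSC": 1.1, "IR": 0.3}
    )
    # selection strength tracks mutational lability (the planted syndrome:
    # fast groups also tolerate more amino-acid change), tightly enough
    # that the rate/GD/variation correlation structure is recoverable
    omega_scale: float = 0.15
    omega_exponent: float = 1.0  # couples omega to the rate multiplier
    omega_sigma: float = 0.15
    omega_bounds: tuple = (0.02, 0.9)
    ndh_loss: bool = True  # drop NDH genes from one clade of taxa
    ndh_clade_size: tuple = (4, 7)
    rpl33_loss: bool = True  # drop rpl33 from two random taxa
    position_freqs: tuple = DEFAULT_POSITION_FREQS


def _template(n_genes: int) -> list[tuple[str, int, str, str]]:
    """(gene, length, group, region) rows from the shipped template."""
    from .rates import GroupingConfig, _read_two_col_text
    from importlib.resources import files

    cfg = GroupingConfig.default()
    lengths = _read_two_col_text(
        files("chloroscape.data").joinpath("gene_lengths.tsv").read_text()
    )
    genes = list(lengths)
    if n_genes > len(genes):
        raise ValueError(f"template has only {len(genes)} genes")
    return [
        (g, int(lengths[g]), cfg.group_map[g], cfg.region_map[g])
        for g in genes[:n_genes]
    ]


def _pick_clade(tree: Tree, size_range: tuple[int, int], rng) -> set[str]:
    candidates = []
    for node in tree.postorder():
        if not node.is_tip and node.parent is not None:
            tips = {n.label for n in Tree(node).tips()}
            if size_range[0] <= len(tips) <= size_range[1]:
                candidates.append(tips)
    if not candidates:
        # fall back to the smallest clade above the minimum size
        sizes = [
            {n.label for n in Tree(node).tips()}
            for node in tree.postorder()
            if not node.is_tip and node.parent is not None
        ]
        candidates = [min(sizes, key=len)] if sizes else []
    if not candidates:
        return set()
    candidates.sort(key=lambda s: tuple(sorted(s)))
    return set(candidates[int(rng.integers(len(candidates)))])


def inject_gene_loss(
    dataset: BenchmarkDataset, gene_names: Sequence[str], taxa: Sequence[str]
) -> BenchmarkDataset:
    """Remove ``taxa`` from the named genes, updating the truth record.

    Genes left with fewer than 4 taxa are flagged unusable for tree
    building. Modifies the dataset in place and returns it.
    """
    species = {n.label for n in dataset.species_tree.tips()}
    unknown_taxa = [t for t in taxa if t not in species]
    if unknown_taxa:
        raise ValueError(f"unknown taxa: {unknown_taxa}")
    for gene in gene_names:
        if gene not in dataset.alignments:
            raise ValueError(f"unknown gene: {gene}")
        aln = dataset.alignments[gene].drop_taxa(taxa)
        dataset.alignments[gene] = aln
        remaining = set(aln.taxa)
        if len(remaining) >= 2:
            dataset.gene_trees[gene] = dataset.gene_trees[gene].prune_to(remaining)
        truth = dataset.truth.genes[gene]
        truth.lost_taxa |= set(taxa)
        if len(remaining) < 4:
            truth.usable = False
    return dataset


def make_benchmark_dataset(
    config: BenchmarkConfig | None = None, seed: int = 0
) -> tuple[BenchmarkDataset, SyntheticTruth]:
    """Generate the full benchmark: species tree, MSC gene trees, codon
    alignments, loss events, and the planted-truth record."""
    cfg = config or BenchmarkConfig()
    template = _template(cfg.n_genes)

    st = simulate_species_tree(
        cfg.n_taxa, birth_rate=1.0, seed=derive_seed(seed, "species_tree")
    )
    st = scale_tree(st, cfg.tree_height_cu / tree_height(st))
    gene_trees_list = simulate_msc_gene_trees(
        st, cfg.n_genes, seed=derive_seed(seed, "msc")
    )

    rng = np.random.default_rng(derive_seed(seed, "gene_params"))
    genes: dict[str, GeneTruth] = {}
    alignments: dict[str, GeneAlignment] = {}
    gene_trees: dict[str, Tree] = {}
    for (gene, length, group, region), gtree in zip(template, gene_trees_list):
        r = (
            cfg.group_base_rate[group]
            * cfg.region_multiplier[region]
            * float(rng.lognormal(0.0, cfg.rate_sigma))
        )
        omega = float(
            np.clip(
                cfg.omega_scale
                * r**cfg.omega_exponent
                * rng.lognormal(0.0, cfg.omega_sigma),
                *cfg.omega_bounds,
            )
        )
        subs_tree = scale_tree(gtree, cfg.subs_per_cu)
        aln = simulate_codon_alignment(
            subs_tree,
            length // 3,
            kappa=cfg.kappa,
            omega=omega,
            codon_freqs=f3x4_frequencies(cfg.position_freqs),
            seed=derive_seed(seed, f"aln:{gene}"),
            rate_multiplier=r,
            name=gene,
        )
        aln.group, aln.region = group, region
        genes[gene] = GeneTruth(length, r, omega, group, region)
        alignments[gene] = aln
        gene_trees[gene] = gtree

    truth = SyntheticTruth(
        species_tree=st,
        genes=genes,
        kappa=cfg.kappa,
        position_freqs=cfg.position_freqs,
        gamma_shape=cfg.gamma_shape,
        seed=seed,
    )
    dataset = BenchmarkDataset(st, alignments, gene_trees, truth)

    loss_rng = np.random.default_rng(derive_seed(seed, "loss"))
    if cfg.ndh_loss:
        clade = _pick_clade(st, cfg.ndh_clade_size, loss_rng)
        ndh_genes = [g for g, tr in genes.items() if tr.group == "NDH"]
        if clade and ndh_genes:
            inject_gene_loss(dataset, ndh_genes, sorted(clade))
    if cfg.rpl33_loss and "rpl33" in alignments:
        all_taxa = sorted(n.label for n in st.tips())
        already_lost = genes["rpl33"].lost_taxa
        pool = [t for t in all_taxa if t not in already_lost]
        pick = loss_rng.choice(len(pool), size=min(2, len(pool)), replace=False)
        inject_gene_loss(dataset, ["rpl33"], [pool[i] for i in sorted(pick)])
    return dataset, truth
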