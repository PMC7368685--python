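"""Genetic variation and Townsend phylogenetic informativeness.

Per-gene statistics: segregating sites S, nucleotide diversity pi (mean
pairwise per-site differences, pairwise deletion), percent variability
PV = S/L, and parsimony-informative site counts. Phylogenetic
informativeness needs per-site substitution rates, estimated here by
per-column JC69 maximum likelihood on a fixed relative-time ultrametric
tree (root depth 1), then profiled over relative time t with Townsend's
quartet formula rho(t; lambda) = 16 lambda^2 t exp(-4 lambda t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import GeneAlignment
from .trees import Tree, root_to_tip_depths

log = logging.getLogger(__name__)

__all__ = [
    "segregating_sites",
    "nucleotide_diversity",
    "percent_variability",
    "parsimony_informative_sites",
    "site_rates",
    "pi_profile",
    "VariationRecord",
    "variation_record",
]

_ACGT = (b"A", b"C", b"G", b"T")


def _state_matrix(aln: GeneAlignment) -> np.ndarray:
    """(n_taxa, L) integer states: 0..3 for ACGT, -1 for gap/ambiguous."""
    M = aln.matrix()
    out = np.full(M.shape, -1, dtype=np.int8)
    for code, b in enumerate(_ACGT):
        out[M == b] = code
    return out


def segregating_sites(aln: GeneAlignment) -> int:
    """Columns with >= 2 distinct states among A/C/G/T (gaps/N ignored)."""
    if aln.n_taxa < 2:
        raise ValueError(f"{aln.name}: need >= 2 sequences")
    S = _state_matrix(aln)
    count = 0
    for col in S.T:
        vals = col[col >= 0]
        if vals.size and (vals != vals[0]).any():
            count += 1
    return count


def nucleotide_diversity(aln: GeneAlignment, complete_deletion: bool = False) -> float:
    """Mean over unordered pairs of per-site differences.

    Gap/ambiguous columns are deleted pairwise by default;
    ``complete_deletion`` drops every column with any gap/ambiguity
    before comparing (the stricter convention some tools default to).
    """
    if aln.n_taxa < 2:
        raise ValueError(f"{aln.name}: need >= 2 sequences")
    S = _state_matrix(aln)
    if complete_deletion:
        S = S[:, (S >= 0).all(axis=0)]
    n = aln.n_taxa
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            both = (S[i] >= 0) & (S[j] >= 0)
            total = int(both.sum())
            if total == 0:
                log.warning(
                    "%s: no comparable columns between %s and %s; pair excluded",
                    aln.name,
                    aln.taxa[i],
                    aln.taxa[j],
                )
                continue
            vals.append(float((S[i, both] != S[j, both]).sum()) / total)
    if not vals:
        raise ValueError(f"{aln.name}: no comparable sequence pair")
    return float(np.mean(vals))


def percent_variability(aln: GeneAlignment) -> float:
    """PV = segregating sites / alignment length."""
    if aln.length < 1:
        raise ValueError(f"{aln.name}: empty alignment")
    return segregating_sites(aln) / aln.length


def parsimony_informative_sites(aln: GeneAlignment) -> int:
    """Columns with >= 2 states each present in >= 2 sequences."""
    if aln.n_taxa < 4:
        raise ValueError(f"{aln.name}: need >= 4 sequences")
    S = _state_matrix(aln)
    count = 0
    for col in S.T:
        vals = col[col >= 0]
        if vals.size == 0:
            continue
        _, freqs = np.unique(vals, return_counts=True)
        if (freqs >= 2).sum() >= 2:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Per-site rates on a fixed clock tree


def _jc_loglik(
    states: np.ndarray,
    tree: Tree,
    taxa: list[str],
    lam: np.ndarray,
) -> np.ndarray:
    """Log-likelihood per column under JC69 at per-column rates ``lam``.

    ``states``: (n_taxa, L) integer matrix; ``lam``: (L,). Felsenstein
    pruning vectorized over columns; JC transition probabilities in closed
    form: p_same = 1/4 + 3/4 exp(-4 lam t / 3).
    """
    L = states.shape[1]
    taxon_row = {t: i for i, t in enumerate(taxa)}
    partial: dict[int, np.ndarray] = {}
    scale = np.zeros(L)
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in taxon_row:
                continue  # tree tip absent from the alignment: no data
            s = states[taxon_row[node.label]]
            p = np.zeros((L, 4))
            known = s >= 0
            p[known, s[known]] = 1.0
            p[~known] = 1.0  # missing data: uninformative
            partial[id(node)] = p
        else:
            acc = None
            for child in node.children:
                if id(child) not in partial:
                    continue
                cp = partial[id(child)]
                t = child.length or 0.0
                e = np.exp(-4.0 * lam * t / 3.0)[:, None]
                same = 0.25 + 0.75 * e
                diff = 0.25 - 0.25 * e
                total = cp.sum(axis=1, keepdims=True)
                msg = diff * total + (same - diff) * cp
                acc = msg if acc is None else acc * msg
            if acc is None:
                continue
            m = acc.max(axis=1)
            m[m == 0] = 1.0
            scale += np.log(m)
            partial[id(node)] = acc / m[:, None]
    root_p = partial[id(tree.root)]
    return np.log(root_p.mean(axis=1)) + scale


@dataclass
class SiteRates:
    """Per-column JC69 rate multipliers on a relative-time clock tree."""

    rates: np.ndarray  # lambda_i >= 0, substitutions/site/unit time
    lam_max: float


def site_rates(
    aln: GeneAlignment,
    clock_tree: Tree,
    lam_max: float = 20.0,
    tol: float = 1e-6,
) -> SiteRates:
    """Per-column ML rate under JC69 on a fixed ultrametric tree.

    The tree's tips must include the alignment's taxa and its root-to-tip
    depths must be equal (relative time, root depth 1 by convention).
    Invariant columns get rate 0; optimization is a vectorized golden
    -section search on [0, lam_max] to absolute tolerance ``tol``.
    """
    depths = root_to_tip_depths(clock_tree)
    vals = np.array(list(depths.values()))
    if vals.max() - vals.min() > 1e-6:
        raise ValueError("clock tree is not ultrametric (root-to-tip spread)")
    missing = set(aln.taxa) - set(depths)
    if missing:
        raise ValueError(f"clock tree lacks alignment taxa: {sorted(missing)}")
    states = _state_matrix(aln)
    L = aln.length
    # invariant columns (ignoring gaps) are rate 0 by definition
    variable = np.zeros(L, dtype=bool)
    for k in range(L):
        col = states[:, k]
        obs = col[col >= 0]
        variable[k] = obs.size > 0 and bool((obs != obs[0]).any())
    rates = np.zeros(L)
    idx = np.where(variable)[0]
    if idx.size:
        sub = states[:, idx]

        def nll(lam_vec: np.ndarray) -> np.ndarray:
            return -_jc_loglik(sub, clock_tree, aln.taxa, lam_vec)

        # vectorized golden-section search; per iteration only one new
        # likelihood evaluation per column is needed (the surviving probe
        # point coincides with one of the new ones by the golden ratio)
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a = np.zeros(idx.size)
        b = np.full(idx.size, float(lam_max))
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = nll(c), nll(d)
        while (b - a).max() > tol:
            take_left = fc < fd
            a = np.where(take_left, a, c)
            b = np.where(take_left, d, b)
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            fe = nll(np.where(take_left, c, d))
            fc, fd = np.where(take_left, fe, fd), np.where(take_left, fc, fe)
        rates[idx] = (a + b) / 2.0
    return SiteRates(rates=rates, lam_max=float(lam_max))


def pi_profile(
    rates: SiteRates, t_grid: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Net phylogenetic informativeness over a relative-time grid.

    Returns (PI values per grid point, profile maximum, argmax t*).
    Per-site informativeness is Townsend's rho(t; lambda) =
    16 lambda^2 t exp(-4 lambda t), summed over sites.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if (t <= 0).any() or (t > 1).any():
        raise ValueError("grid times must lie in (0, 1]")
    lam = rates.rates[:, None]
    prof = (16.0 * lam**2 * t[None, :] * np.exp(-4.0 * lam * t[None, :])).sum(axis=0)
    k = int(np.argmax(prof))
    return prof, float(prof[k]), float(t[k])


@dataclass
class VariationRecord:
    """Per-gene variation summary (the Table-S2-style row)."""

    gene: str
    length: int
    S: int
    pi: float
    PV: float
    PI_max: float
    t_star: float


def variation_record(
    aln: GeneAlignment,
    clock_tree: Tree,
    t_grid: np.ndarray | None = None,
    lam_max: float = 20.0,
) -> tuple[VariationRecord, np.ndarray, np.ndarray]:
    """All variation statistics for one gene; returns the record plus the
    (t_grid, PI profile) arrays."""
    if t_grid is None:
        t_grid = np.linspace(0.01, 1.0, 100)
    sr = site_rates(aln, clock_tree, lam_max=lam_max)
    prof, pi_max, t_star = pi_profile(sr, t_grid)
    return (
        VariationRecord(
            gene=aln.name,
            length=aln.length,
            S=segregating_sites(aln),
            pi=nucleotide_diversity(aln),
            PV=percent_variability(aln),
            PI_max=pi_max,
            t_star=t_star,
        ),
        np.asarray(t_grid),
        prof,
    )
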