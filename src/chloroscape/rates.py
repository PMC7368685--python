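"""Counting-based synonymous/nonsynonymous substitution rates (NG86).

Implements Nei-Gojobori (1986) site and difference counting with pathway
averaging for multi-difference codons, mutational paths through stop
codons excluded, and Jukes-Cantor multiple-hit correction:

    d = -(3/4) * ln(1 - (4/3) p)

Rates are aggregated per gene as the mean over all sequence pairs, and
per functional group / plastome region after codon-respecting
concatenation. The universal genetic code is used throughout (plastid
protein-coding genes follow it).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alignment import GeneAlignment, concatenate

__all__ = [
    "CODONS",
    "GENETIC_CODE",
    "ng86_sites",
    "ng86_pair",
    "unit_rates",
    "group_region_rates",
    "RatesRecord",
    "GroupingConfig",
    "jc_correct",
]

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)

#: codon -> amino acid (one letter; '*' = stop), universal code
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

#: the 61 sense codons, sorted alphabetically
CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
STOPS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


def ng86_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    Each of the nine single-nucleotide changes contributes 1/3 site to the
    synonymous or nonsynonymous total; changes creating a stop codon are
    excluded entirely, so the two counts sum to (9 - #stop neighbours)/3.
    """
    codon = codon.upper()
    if codon not in CODON_INDEX:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    syn = nonsyn = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = GENETIC_CODE[alt]
            if alt_aa == "*":
                continue
            if alt_aa == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two sense codons.

    Multi-difference codons are averaged over all orderings of the
    single-step pathways; pathways passing through a stop codon are
    excluded. In the (rare) event every pathway is blocked, all pathways
    are used with stop intermediates scored as nonsynonymous steps.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool) -> tuple[float, float] | None:
        syn = nonsyn = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != c2 and not allow_stops:
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    results = [
        r
        for order in itertools.permutations(diff)
        if (r := walk(order, allow_stops=False)) is not None
    ]
    if not results:
        results = [walk(order, allow_stops=True) for order in itertools.permutations(diff)]
    syn = sum(r[0] for r in results) / len(results)
    nonsyn = sum(r[1] for r in results) / len(results)
    return syn, nonsyn


_SITE_TABLE: np.ndarray | None = None
_PAIR_TABLE: np.ndarray | None = None


def _tables() -> tuple[np.ndarray, np.ndarray]:
    global _SITE_TABLE, _PAIR_TABLE
    if _SITE_TABLE is None:
        _SITE_TABLE = np.array([ng86_sites(c) for c in CODONS])
        pair = np.zeros((61, 61, 2))
        for i, ci in enumerate(CODONS):
            for j in range(i + 1, 61):
                pair[i, j] = pair[j, i] = _pathway_counts(ci, CODONS[j])
        _PAIR_TABLE = pair
    return _SITE_TABLE, _PAIR_TABLE


def jc_correct(p: float) -> float | None:
    """Jukes-Cantor correction; ``None`` when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _codon_indices(seq: str) -> np.ndarray:
    """Codon index per frame position; -1 for gap/N/stop/ambiguous codons."""
    n = len(seq) // 3
    out = np.full(n, -1, dtype=np.int64)
    s = seq.upper()
    for k in range(n):
        out[k] = CODON_INDEX.get(s[3 * k : 3 * k + 3], -1)
    return out


@dataclass
class PairwiseNG86:
    dN: float | None
    dS: float | None
    omega: float | None
    Nd: float
    Sd: float
    N: float
    S: float
    n_codons: int


def ng86_pair(seq1: str, seq2: str) -> PairwiseNG86:
    """NG86 dN, dS and dN/dS between two in-frame codon sequences.

    Codons with gaps, ambiguity codes or stops in either sequence are
    skipped pairwise (mirrors complete-deletion ``cleandata`` handling at
    the pair level). A proportion p >= 3/4 leaves that rate missing.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3 != 0:
        raise ValueError("sequence length not divisible by 3")
    site_tab, pair_tab = _tables()
    i1 = _codon_indices(seq1)
    i2 = _codon_indices(seq2)
    ok = (i1 >= 0) & (i2 >= 0)
    a, b = i1[ok], i2[ok]
    n_codons = int(ok.sum())
    if n_codons == 0:
        return PairwiseNG86(None, None, None, 0.0, 0.0, 0.0, 0.0, 0)
    sites = 0.5 * (site_tab[a] + site_tab[b]).sum(axis=0)
    S, N = float(sites[0]), float(sites[1])
    diffs = pair_tab[a, b].sum(axis=0)
    Sd, Nd = float(diffs[0]), float(diffs[1])
    dS = jc_correct(Sd / S) if S > 0 else None
    dN = jc_correct(Nd / N) if N > 0 else None
    omega = None
    if dN is not None and dS is not None and dS > 0:
        omega = dN / dS
    return PairwiseNG86(dN, dS, omega, Nd, Sd, N, S, n_codons)


@dataclass
class RatesRecord:
    """dN/dS summary for one unit (gene, functional group, or region)."""

    unit: str
    dN: float | None
    dS: float | None
    omega: float | None
    n_pairs: int


def _mean(vals: list[float]) -> float | None:
    return sum(vals) / len(vals) if vals else None


def unit_rates(aln: GeneAlignment, unit: str | None = None) -> RatesRecord:
    """Mean pairwise NG86 rates over all sequence pairs of an alignment.

    Pairs with a missing value are excluded from that rate's mean; a unit
    with no valid pair at all gets a record with every field missing.
    """
    if aln.n_taxa < 2:
        raise ValueError(f"{aln.name}: need >= 2 sequences")
    dns, dss, oms = [], [], []
    n_pairs = 0
    for s1, s2 in itertools.combinations(aln.sequences, 2):
        pair = ng86_pair(s1, s2)
        if pair.n_codons == 0:
            continue
        n_pairs += 1
        if pair.dN is not None:
            dns.append(pair.dN)
        if pair.dS is not None:
            dss.append(pair.dS)
        if pair.omega is not None:
            oms.append(pair.omega)
    return RatesRecord(unit or aln.name, _mean(dns), _mean(dss), _mean(oms), n_pairs)


@dataclass
class GroupingConfig:
    """Gene -> functional group and gene -> plastome region maps."""

    group_map: dict[str, str]
    region_map: dict[str, str]

    def validate(self, genes: Iterable[str]) -> None:
        missing = [
            g for g in genes if g not in self.group_map or g not in self.region_map
        ]
        if missing:
            raise ValueError(f"genes missing from grouping config: {missing}")

    @classmethod
    def from_tsv(cls, group_path, region_path) -> "GroupingConfig":
        return cls(_read_two_col(group_path), _read_two_col(region_path))

    @classmethod
    def default(cls) -> "GroupingConfig":
        """The shipped plastome template (functional groups and regions)."""
        from importlib.resources import files

        data = files("chloroscape.data")
        return cls(
            _read_two_col_text(data.joinpath("gene_groups.tsv").read_text()),
            _read_two_col_text(data.joinpath("gene_regions.tsv").read_text()),
        )


def _read_two_col_text(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene, value = line.split("\t")[:2]
        if gene in out:
            raise ValueError(f"gene {gene} mapped twice")
        out[gene] = value
    return out


def _read_two_col(path) -> dict[str, str]:
    with open(path) as fh:
        return _read_two_col_text(fh.read())


def group_region_rates(
    genes: Sequence[GeneAlignment], cfg: GroupingConfig
) -> list[RatesRecord]:
    """One NG86 record per functional group and per plastome region.

    Genes are concatenated codon-respectingly within each unit; taxa
    missing a gene contribute gap codons that are skipped pairwise.
    """
    cfg.validate(g.name for g in genes)
    records: list[RatesRecord] = []
    for mapping, kind in ((cfg.group_map, "group"), (cfg.region_map, "region")):
        units: dict[str, list[GeneAlignment]] = {}
        for g in genes:
            units.setdefault(mapping[g.name], []).append(g)
        for unit in sorted(units):
            supermatrix, _ = concatenate(units[unit])
            records.append(unit_rates(supermatrix, unit=unit))
    return records
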