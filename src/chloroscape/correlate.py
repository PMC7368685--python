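"""Pearson correlation of substitution rates with gene characteristics.

Reproduces the 12-panel design relating each rate measure (dN, dS,
dN/dS) to gene-tree discordance (GD), nucleotide diversity (pi), percent
variability (PV) and phylogenetic informativeness (PI). Genes with a
missing value in either variable of a panel are excluded pairwise; raw
two-sided p-values from the Student-t reference distribution are
reported with conventional significance stars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["pearson_test", "rates_vs_characteristics", "CorrelationResult"]

#: panel order: rows = characteristics, columns = rate measures
PANEL_ROWS = ("GD", "pi", "PV", "PI")
PANEL_COLS = ("dN", "dS", "omega")


@dataclass
class CorrelationResult:
    x: str
    y: str
    n: int
    r: float
    t: float
    df: int
    p: float
    stars: str

    def to_row(self) -> str:
        return (
            f"{self.x}\t{self.y}\t{self.n}\t{self.r:.6g}\t{self.t:.6g}\t"
            f"{self.df}\t{self.p:.6g}\t{self.stars}"
        )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pearson_test(
    x: Sequence[float], y: Sequence[float], x_name: str = "x", y_name: str = "y"
) -> CorrelationResult:
    """Pearson r with the t-based two-sided p-value.

    Missing values (None/NaN) are removed pairwise; requires n >= 3
    non-missing pairs and non-constant variables.
    """
    xv = np.array([math.nan if v is None else float(v) for v in x])
    yv = np.array([math.nan if v is None else float(v) for v in y])
    ok = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[ok], yv[ok]
    n = xv.size
    if n < 3:
        raise ValueError(f"{x_name} vs {y_name}: need >= 3 complete pairs, got {n}")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError(f"{x_name} vs {y_name}: constant variable")
    xc, yc = xv - xv.mean(), yv - yv.mean()
    r = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(x_name, y_name, n, r, t, df, p, _stars(p))


def rates_vs_characteristics(
    profiles: Sequence[dict] | "object",
    holm: bool = False,
) -> list[CorrelationResult]:
    """The 12 panels {GD, pi, PV, PI} x {dN, dS, omega}, in panel order
    a-l (row-major: GD x three rates first).

    ``profiles`` is a sequence of per-gene mappings (or objects) carrying
    the keys/attributes dN, dS, omega, GD, pi, PV, PI. ``holm`` applies a
    Holm step-down correction across the 12 p-values (off by default: the
    analysis convention is raw p-values at the 0.05 cutoff).
    """

    def get(rec, key):
        if isinstance(rec, dict):
            if key not in rec:
                raise KeyError(f"profile missing column {key!r}")
            return rec[key]
        if not hasattr(rec, key):
            raise KeyError(f"profile missing column {key!r}")
        return getattr(rec, key)

    records = list(profiles)
    results = []
    for row in PANEL_ROWS:
        for col in PANEL_COLS:
            results.append(
                pearson_test(
                    [get(r, row) for r in records],
                    [get(r, col) for r in records],
                    x_name=row,
                    y_name=col,
                )
            )
    if holm:
        order = np.argsort([res.p for res in results])
        m = len(results)
        prev = 0.0
        for rank, i in enumerate(order):
            adj = min(1.0, (m - rank) * results[i].p)
            adj = max(adj, prev)
            prev = adj
            results[i].p = adj
            results[i].stars = _stars(adj)
    return results


def correlations_tsv(results: Sequence[CorrelationResult]) -> str:
    lines = ["x\ty\tn\tr\tt\tdf\tp\tstars"]
    lines.extend(res.to_row() for res in results)
    return "\n".join(lines) + "\n"
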