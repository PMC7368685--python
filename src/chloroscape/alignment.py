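"""Per-gene multiple sequence alignments and concatenation.

A :class:`GeneAlignment` is the in-memory unit passed between pipeline
stages: equal-length sequences over ``ACGTN-`` (codon genes are kept in
frame, length divisible by 3), plus the gene's functional-group and
plastome-region labels used by the grouping stages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneAlignment:
    """An aligned gene: taxa (rows) by sites (columns)."""

    name: str
    taxa: list[str]
    sequences: list[str]
    is_codon: bool = True
    group: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError(f"{self.name}: taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"{self.name}: duplicate taxon names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.name}: ragged alignment, row lengths {sorted(lengths)}"
            )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def matrix(self) -> np.ndarray:
        """(n_taxa, length) array of single-byte characters."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n_taxa, self.length)

    def sequence_of(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def subset_taxa(self, taxa: Iterable[str]) -> "GeneAlignment":
        keep = [t for t in self.taxa if t in set(taxa)]
        return GeneAlignment(
            self.name,
            keep,
            [self.sequence_of(t) for t in keep],
            is_codon=self.is_codon,
            group=self.group,
            region=self.region,
        )

    def drop_taxa(self, taxa: Iterable[str]) -> "GeneAlignment":
        drop = set(taxa)
        return self.subset_taxa([t for t in self.taxa if t not in drop])

    def check_frame(self) -> None:
        """Require length % 3 == 0 and no internal stop in any full row."""
        if self.length % 3 != 0:
            raise ValueError(
                f"{self.name}: length {self.length} not divisible by 3"
            )
        for taxon, seq in zip(self.taxa, self.sequences):
            for i in range(0, self.length - 3, 3):  # final codon may be a stop
                codon = seq[i : i + 3].upper()
                if codon in STOP_CODONS:
                    raise ValueError(
                        f"{self.name}: internal stop codon {codon} at "
                        f"position {i + 1} in row {taxon}"
                    )


def read_fasta_alignment(path, name: str | None = None, **kw) -> GeneAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA")
    gene = name or os.path.splitext(os.path.basename(str(path)))[0]
    return GeneAlignment(
        gene,
        [r.id for r in records],
        [str(r.seq).upper() for r in records],
        **kw,
    )


def write_fasta_alignment(path, aln: GeneAlignment) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def concatenate(
    genes: Sequence[GeneAlignment], taxa: Sequence[str] | None = None
) -> tuple[GeneAlignment, list[tuple[str, int, int]]]:
    """Column-wise concatenation in the given gene order.

    Taxa missing from a gene receive gap runs of that gene's length.
    Returns the supermatrix and a partition table of 1-based inclusive
    coordinate ranges ``(gene, start, end)``.
    """
    if not genes:
        raise ValueError("nothing to concatenate")
    if taxa is None:
        taxa = sorted({t for g in genes for t in g.taxa})
    taxa = list(taxa)
    taxon_set = set(taxa)
    for g in genes:
        unknown = [t for t in g.taxa if t not in taxon_set]
        if unknown:
            raise ValueError(f"{g.name}: taxa {unknown} not in the taxon list")
    rows = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    pos = 0
    for g in genes:
        partitions.append((g.name, pos + 1, pos + g.length))
        pos += g.length
        lookup = dict(zip(g.taxa, g.sequences))
        gaps = "-" * g.length
        for t in taxa:
            rows[t].append(lookup.get(t, gaps))
    name = genes[0].name if len(genes) == 1 else "concatenation"
    return (
        GeneAlignment(
            name,
            taxa,
            ["".join(rows[t]) for t in taxa],
            is_codon=all(g.is_codon for g in genes),
        ),
        partitions,
    )
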