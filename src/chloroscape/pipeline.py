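"""Pipeline orchestration: from alignments (real or simulated) to the
per-gene profile table, tree-space ordination, PCS, rates, variation and
the 12-panel correlation report.

Every run is driven by a :class:`PipelineConfig` holding either a
real-input block (alignment directory, gene trees, species tree(s),
grouping maps) or a simulation block (benchmark generator settings); the
single seed deterministically drives every stochastic stage through
stage-name-derived sub-seeds, and all outputs are plain TSV so identical
configurations yield byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np

from . import __version__
from .alignment import GeneAlignment, read_fasta_alignment
from .correlate import correlations_tsv, rates_vs_characteristics
from .inference import jc_distance_matrix, neighbor_joining
from .pcs import PCSTable, pcs_scores
from .rates import GroupingConfig, RatesRecord, group_region_rates, unit_rates
from .simulate import BenchmarkConfig, derive_seed, make_benchmark_dataset
from .trees import Tree, parse_newick, ultrametricize
from .treespace import gene_discordance, pcoa, restrict_to_common_taxa, rf_matrix
from .variation import variation_record

log = logging.getLogger(__name__)

__all__ = [
    "GeneProfile",
    "PipelineConfig",
    "PipelineResult",
    "load_gene_alignments",
    "run_pipeline",
]

SPECIES_COALESCENT_ID = "species_coalescent"
SPECIES_ALT_ID = "species_concatenation"

_NA = "NA"


def _fmt(v: Any) -> str:
    if v is None:
        return _NA
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


@dataclass
class GeneProfile:
    """One row of the merged per-gene report (Table-S2-style)."""

    gene: str
    group: str | None = None
    region: str | None = None
    n_taxa: int | None = None
    L: int | None = None
    S: int | None = None
    pi: float | None = None
    PV: float | None = None
    PI: float | None = None
    t_star: float | None = None
    GD: float | None = None
    PCS: int | None = None
    PCS_class: str | None = None
    dN: float | None = None
    dS: float | None = None
    omega: float | None = None

    COLUMNS = (
        "gene group region n_taxa L S pi PV PI t_star GD PCS PCS_class dN dS omega"
    ).split()

    def to_row(self) -> str:
        return "\t".join(_fmt(getattr(self, c)) for c in self.COLUMNS)


@dataclass
class PipelineConfig:
    """Exactly one of ``inputs`` (real data) or ``simulation`` must be set."""

    seed: int = 0
    out_dir: str = "chloroscape_out"
    inputs: dict | None = None  # alignments_dir, gene_trees, gene_tree_ids,
    # species_tree, species_tree_alt?, group_tsv, region_tsv
    simulation: dict | None = None  # BenchmarkConfig field overrides
    rf_normalized: bool = False
    d_max: float = 5.0
    lam_max: float = 20.0
    pcs_mode: str = "nni"  # or "alt" to use the alternative species tree
    frame_check: bool = True
    blind_species_tree: bool = False  # synthetic mode: NJ on concatenation
    t_grid_points: int = 100

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError(
                "config must contain exactly one of an input block or a "
                "simulation block"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded
        so identical analyses give identical run logs)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_gene_alignments(directory, frame_check: bool = True) -> list[GeneAlignment]:
    """One FASTA per gene (filename stem = gene name), validated."""
    genes = []
    for fname in sorted(os.listdir(directory)):
        if not fname.endswith((".fa", ".fasta", ".fas")):
            continue
        aln = read_fasta_alignment(os.path.join(directory, fname))
        if frame_check:
            aln.check_frame()
        genes.append(aln)
    if not genes:
        raise ValueError(f"no FASTA alignments found in {directory}")
    return genes


@dataclass
class PipelineResult:
    profiles: list[GeneProfile]
    ordination: Any
    discordance: Any
    pcs: PCSTable
    gene_rates: list[RatesRecord]
    unit_rates: list[RatesRecord]
    correlations: list
    exclusions: dict[str, str]
    prune_report: dict
    out_dir: str
    variation: dict = None
    pi_profiles: dict = None
    t_grid: Any = None

    def profile_tsv(self) -> str:
        lines = ["\t".join(GeneProfile.COLUMNS)]
        lines.extend(p.to_row() for p in sorted(self.profiles, key=lambda p: p.gene))
        return "\n".join(lines) + "\n"


def _estimate_gene_trees(
    alignments: dict[str, GeneAlignment], d_max: float
) -> tuple[dict[str, Tree], dict[str, str]]:
    trees: dict[str, Tree] = {}
    excluded: dict[str, str] = {}
    for gene, aln in alignments.items():
        if aln.n_taxa < 4:
            excluded[gene] = "fewer-than-4-taxa"
            continue
        try:
            trees[gene] = neighbor_joining(jc_distance_matrix(aln, d_max=d_max))
        except ValueError as exc:
            excluded[gene] = f"distance-failure: {exc}"
    return trees, excluded


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write the report bundle to
    ``cfg.out_dir``. See the module docstring for the stage list."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    run_log: list[str] = [
        f"chloroscape {__version__}",
        f"seed {cfg.seed}",
        f"config-digest {cfg.digest()}",
    ]
    exclusions: dict[str, str] = {}

    # ---- inputs ----------------------------------------------------------
    if cfg.simulation is not None:
        bench_cfg = BenchmarkConfig(**cfg.simulation)
        dataset, truth = make_benchmark_dataset(bench_cfg, seed=cfg.seed)
        alignments = dict(dataset.alignments)
        grouping = GroupingConfig.default()
        species_tree = dataset.species_tree
        species_alt: Tree | None = None
        run_log.append(
            f"simulated benchmark: {len(alignments)} genes, "
            f"{bench_cfg.n_taxa} taxa"
        )
        for gene, gt in truth.genes.items():
            if gt.lost_taxa:
                run_log.append(
                    f"gene loss: {gene} lacks {','.join(sorted(gt.lost_taxa))}"
                )
        gene_trees, excluded = _estimate_gene_trees(alignments, cfg.d_max)
        exclusions.update(excluded)
        if cfg.blind_species_tree:
            from .alignment import concatenate

            supermatrix, _ = concatenate(list(alignments.values()))
            species_tree = neighbor_joining(
                jc_distance_matrix(supermatrix, d_max=cfg.d_max)
            )
            run_log.append("species tree: NJ on the concatenation (blind mode)")
        else:
            run_log.append("species tree: true simulated tree")
    else:
        inp = cfg.inputs
        alignments = {
            a.name: a
            for a in load_gene_alignments(
                inp["alignments_dir"], frame_check=cfg.frame_check
            )
        }
        species_tree = parse_newick(open(inp["species_tree"]).read())
        species_alt = None
        if inp.get("species_tree_alt"):
            species_alt = parse_newick(open(inp["species_tree_alt"]).read())
        if inp.get("gene_trees"):
            from .trees import read_newick_file

            tree_list = read_newick_file(inp["gene_trees"])
            with open(inp["gene_tree_ids"]) as fh:
                ids = [line.strip() for line in fh if line.strip()]
            if len(ids) != len(tree_list):
                raise ValueError("gene tree ids do not match tree count")
            gene_trees = dict(zip(ids, tree_list))
        else:
            gene_trees, excluded = _estimate_gene_trees(alignments, cfg.d_max)
            exclusions.update(excluded)
        if inp.get("group_tsv"):
            grouping = GroupingConfig.from_tsv(inp["group_tsv"], inp["region_tsv"])
        else:
            grouping = GroupingConfig.default()

    # ---- tree space / GD -------------------------------------------------
    trees_for_space: dict[str, Tree] = dict(gene_trees)
    trees_for_space[SPECIES_COALESCENT_ID] = species_tree
    if cfg.simulation is None and species_alt is not None:
        trees_for_space[SPECIES_ALT_ID] = species_alt
    pruned, prune_report = restrict_to_common_taxa(trees_for_space)
    for key in prune_report["dropped_trees"]:
        if key not in (SPECIES_COALESCENT_ID, SPECIES_ALT_ID):
            exclusions[key] = "pruned-to-fewer-than-4-taxa"
    run_log.append(
        "tree space: "
        f"{len(prune_report['common_taxa'])} common taxa; removed taxa "
        f"{prune_report['removed_taxa'] or 'none'}; dropped trees "
        f"{prune_report['dropped_trees'] or 'none'}"
    )
    if SPECIES_COALESCENT_ID not in pruned:
        raise RuntimeError("species tree lost in pruning; cannot compute GD")
    D = rf_matrix(pruned, normalized=cfg.rf_normalized)
    ordination = pcoa(D, k=2)
    discordance = gene_discordance(
        ordination,
        SPECIES_COALESCENT_ID,
        exclude=(SPECIES_ALT_ID,),
    )

    # ---- PCS -------------------------------------------------------------
    pcs_genes = {g: t for g, t in gene_trees.items()}
    if cfg.pcs_mode == "alt" and species_alt is not None:
        pcs_table = pcs_scores(pcs_genes, species_tree, alternatives=[species_alt])
    else:
        pcs_table = pcs_scores(pcs_genes, species_tree, alternatives="nni")
    run_log.append(f"PCS aggregation: {pcs_table.mode}")

    # ---- substitution rates ---------------------------------------------
    gene_rates: list[RatesRecord] = []
    rate_by_gene: dict[str, RatesRecord] = {}
    codon_genes = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        if not aln.is_codon:
            continue
        if aln.n_taxa < 2:
            exclusions.setdefault(gene, "fewer-than-2-taxa")
            continue
        rec = unit_rates(aln)
        gene_rates.append(rec)
        rate_by_gene[gene] = rec
        codon_genes.append(aln)
    grouping.validate(a.name for a in codon_genes)
    units = group_region_rates(codon_genes, grouping)

    # ---- variation / informativeness ------------------------------------
    clock_tree = ultrametricize(species_tree)
    t_grid = np.linspace(1.0 / cfg.t_grid_points, 1.0, cfg.t_grid_points)
    variation: dict[str, Any] = {}
    profile_rows: dict[str, np.ndarray] = {}
    for gene in sorted(alignments):
        aln = alignments[gene]
        if aln.n_taxa < 2:
            continue
        rec, _, prof = variation_record(
            aln, clock_tree, t_grid=t_grid, lam_max=cfg.lam_max
        )
        variation[gene] = rec
        profile_rows[gene] = prof

    # ---- merge profiles --------------------------------------------------
    profiles: list[GeneProfile] = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        p = GeneProfile(
            gene=gene,
            group=grouping.group_map.get(gene),
            region=grouping.region_map.get(gene),
            n_taxa=aln.n_taxa,
            L=aln.length,
        )
        if gene in variation:
            v = variation[gene]
            p.S, p.pi, p.PV, p.PI, p.t_star = v.S, v.pi, v.PV, v.PI_max, v.t_star
        if gene in discordance.gd:
            p.GD = discordance.gd[gene]
        if gene in pcs_table.pcs:
            p.PCS = pcs_table.pcs[gene]
            p.PCS_class = pcs_table.sign[gene]
        if gene in rate_by_gene:
            rec = rate_by_gene[gene]
            p.dN, p.dS, p.omega = rec.dN, rec.dS, rec.omega
        profiles.append(p)
        if (
            gene not in exclusions
            and rate_by_gene.get(gene) is not None
            and rate_by_gene[gene].dN is None
            and rate_by_gene[gene].dS is None
        ):
            exclusions[gene] = "all-missing-rates"

    # ---- correlations ----------------------------------------------------
    correlations = rates_vs_characteristics(
        [p for p in profiles if p.GD is not None]
    )

    for gene, reason in sorted(exclusions.items()):
        run_log.append(f"excluded: {gene} ({reason})")

    result = PipelineResult(
        profiles=profiles,
        ordination=ordination,
        discordance=discordance,
        pcs=pcs_table,
        gene_rates=gene_rates,
        unit_rates=units,
        correlations=correlations,
        exclusions=exclusions,
        prune_report=prune_report,
        out_dir=cfg.out_dir,
        variation=variation,
        pi_profiles=profile_rows,
        t_grid=t_grid,
    )
    _write_bundle(result, run_log, cfg)
    return result


def _write_bundle(res: PipelineResult, run_log: list[str], cfg: PipelineConfig) -> None:
    out = res.out_dir

    def write(name: str, text: str) -> None:
        with open(os.path.join(out, name), "w") as fh:
            fh.write(text)

    write("profile.tsv", res.profile_tsv())
    ord_lines = ["id\t" + "\t".join(
        f"axis{i + 1}" for i in range(res.ordination.coordinates.shape[1])
    )]
    for i, item in enumerate(res.ordination.ids):
        coords = "\t".join(f"{x:.10g}" for x in res.ordination.coordinates[i])
        ord_lines.append(f"{item}\t{coords}")
    write("ordination.tsv", "\n".join(ord_lines) + "\n")
    eig_lines = ["axis\teigenvalue\tvariance_explained"]
    var = res.ordination.variance_explained
    for i, ev in enumerate(res.ordination.eigenvalues):
        ve = f"{var[i]:.10g}" if i < len(var) else _NA
        eig_lines.append(f"{i + 1}\t{ev:.10g}\t{ve}")
    write("eigenvalues.tsv", "\n".join(eig_lines) + "\n")
    write("discordance.tsv", res.discordance.to_tsv())
    write("pcs.tsv", res.pcs.to_tsv())
    write("pcs_per_clade.tsv", res.pcs.per_clade_tsv())
    rate_lines = ["unit\tdN\tdS\tomega\tn_pairs"]
    for rec in res.gene_rates + res.unit_rates:
        rate_lines.append(
            f"{rec.unit}\t{_fmt(rec.dN)}\t{_fmt(rec.dS)}\t"
            f"{_fmt(rec.omega)}\t{rec.n_pairs}"
        )
    write("rates.tsv", "\n".join(rate_lines) + "\n")
    var_lines = ["gene\tL\tS\tpi\tPV\tPI_max\tt_star"]
    for gene in sorted(res.variation or {}):
        v = res.variation[gene]
        var_lines.append(
            f"{gene}\t{v.length}\t{v.S}\t{_fmt(v.pi)}\t{_fmt(v.PV)}\t"
            f"{_fmt(v.PI_max)}\t{_fmt(v.t_star)}"
        )
    write("variation.tsv", "\n".join(var_lines) + "\n")
    prof_lines = ["gene\tt\tPI"]
    for gene in sorted(res.pi_profiles or {}):
        for t, v in zip(res.t_grid, res.pi_profiles[gene]):
            prof_lines.append(f"{gene}\t{_fmt(float(t))}\t{_fmt(float(v))}")
    write("pi_profiles.tsv", "\n".join(prof_lines) + "\n")
    write("correlations.tsv", correlations_tsv(res.correlations))
    excl_lines = ["gene\treason"]
    for gene in sorted(res.exclusions):
        excl_lines.append(f"{gene}\t{res.exclusions[gene]}")
    write("exclusions.tsv", "\n".join(excl_lines) + "\n")
    write("run_log.txt", "\n".join(run_log) + "\n")
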