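"""Synthetic-data generator: species trees, MSC, sequence models, loss."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import spearmanr

from chloroscape.rates import CODONS, ng86_pair
from chloroscape.simulate import (
    BenchmarkConfig,
    derive_seed,
    f3x4_frequencies,
    gy94_matrix,
    hky_matrix,
    inject_gene_loss,
    make_benchmark_dataset,
    simulate_codon_alignment,
    simulate_msc_gene_trees,
    simulate_nt_alignment,
    simulate_species_tree,
)
from chloroscape.trees import parse_newick, root_to_tip_depths, write_newick


class TestSpeciesTree:
    def test_three_taxa_shape(self):
        t = simulate_species_tree(3, seed=0)
        assert t.n_tips == 3
        internal = [n for n in t.postorder() if not n.is_tip and n.parent]
        assert len(internal) == 1

    @pytest.mark.parametrize("n", [3, 5, 12])
    def test_ultrametric_with_n_tips(self, n):
        t = simulate_species_tree(n, seed=1)
        assert t.n_tips == n
        depths = np.array(list(root_to_tip_depths(t).values()))
        assert depths.std() < 1e-9

    def test_reproducible(self):
        a = simulate_species_tree(8, seed=42)
        b = simulate_species_tree(8, seed=42)
        assert write_newick(a) == write_newick(b)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            simulate_species_tree(2, seed=0)


def _first_cherry(gene_tree):
    for n in gene_tree.postorder():
        if not n.is_tip and len(n.children) == 2 and all(
            c.is_tip for c in n.children
        ):
            return frozenset(c.label for c in n.children)
    return None


class TestMSC:
    def test_long_branches_concordant(self):
        st = parse_newick("((A:100,B:100):100,C:200);")
        for g in simulate_msc_gene_trees(st, 200, seed=0):
            assert _first_cherry(g) == frozenset({"A", "B"})

    @pytest.mark.parametrize("T", [0.5, 1.0, 2.0])
    def test_concordance_calibration(self, T):
        # P(concordant 3-taxon gene tree) = 1 - (2/3) e^{-T}
        st = parse_newick(f"((A:{T},B:{T}):{T},C:{2 * T});")
        n = 10_000
        trees = simulate_msc_gene_trees(st, n, seed=123)
        frac = np.mean([_first_cherry(g) == frozenset({"A", "B"}) for g in trees])
        expected = 1.0 - (2.0 / 3.0) * math.exp(-T)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_star_like_symmetry(self):
        # vanishing internal branch: the three resolutions are equiprobable
        eps = 1e-9
        st = parse_newick(f"((A:{1 + eps},B:{1 + eps}):{eps},C:{1 + 2 * eps});")
        trees = simulate_msc_gene_trees(st, 10_000, seed=7)
        counts = {}
        for g in trees:
            counts[_first_cherry(g)] = counts.get(_first_cherry(g), 0) + 1
        for pair in (
            frozenset({"A", "B"}),
            frozenset({"A", "C"}),
            frozenset({"B", "C"}),
        ):
            assert abs(counts[pair] / 10_000 - 1 / 3) < 0.02

    def test_nonpositive_branch_rejected(self):
        with pytest.raises(ValueError):
            simulate_msc_gene_trees(parse_newick("((A:1,B:0):1,C:2);"), 1, seed=0)

    def test_coalescent_units_and_tipset(self):
        st = simulate_species_tree(6, seed=3)
        gts = simulate_msc_gene_trees(st, 5, seed=4)
        assert all(g.tip_labels() == st.tip_labels() for g in gts)


class TestNucleotideSimulation:
    def test_zero_lengths_identical(self):
        t = parse_newick("((A:0,B:0):0,C:0);")
        aln = simulate_nt_alignment(t, 500, seed=0)
        assert len(set(aln.sequences)) == 1

    def test_two_taxon_pdistance_matches_hky_closed_form(self):
        kappa, pi = 3.0, np.array([0.35, 0.15, 0.2, 0.3])
        t_total = 0.3
        tree = parse_newick(f"(A:{t_total / 2},B:{t_total / 2});")
        aln = simulate_nt_alignment(
            tree, 100_000, kappa=kappa, base_freqs=pi, seed=11
        )
        M = aln.matrix()
        p_obs = float((M[0] != M[1]).mean())
        P = expm(hky_matrix(kappa, pi) * t_total)
        p_exp = float(1.0 - (pi * np.diag(P)).sum())
        assert abs(p_obs - p_exp) < 0.02

    def test_stationary_base_composition(self):
        pi = np.array([0.4, 0.1, 0.2, 0.3])
        tree = parse_newick("(A:0.5,B:0.5);")
        aln = simulate_nt_alignment(tree, 100_000, base_freqs=pi, seed=12)
        M = aln.matrix()
        for base, f in zip(b"ACGT", pi):
            obs = (M == bytes([base])).mean()
            assert abs(obs - f) < 0.01

    def test_invalid_freqs_rejected(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            simulate_nt_alignment(tree, 100, base_freqs=(0.5, 0.5, 0.2, -0.2))
        with pytest.raises(ValueError):
            simulate_nt_alignment(tree, 100, base_freqs=(0.4, 0.4, 0.4, 0.4))


class TestCodonSimulation:
    def test_only_sense_codons_emitted(self):
        tree = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        aln = simulate_codon_alignment(tree, 200, omega=0.5, seed=1)
        sense = set(CODONS)
        for seq in aln.sequences:
            for k in range(0, len(seq), 3):
                assert seq[k : k + 3] in sense

    def test_tiny_omega_suppresses_nonsynonymous_differences(self):
        # no single nonsynonymous substitution ever happens; the only Nd
        # NG86 can report comes from pathway-averaging multi-hit codons,
        # which vanishes with divergence
        tree = parse_newick("(A:0.05,B:0.05);")
        aln = simulate_codon_alignment(tree, 2000, omega=1e-9, seed=2)
        pair = ng86_pair(aln.sequences[0], aln.sequences[1])
        assert pair.Sd > 0
        assert pair.Nd <= 0.02 * pair.Sd
        assert pair.dN <= 0.01 * pair.dS

    def test_two_taxon_matches_transition_probability_oracle(self):
        # brute force: empirical codon-transition frequencies vs expm(Q t)
        kappa, omega = 2.0, 0.3
        pi = f3x4_frequencies(((0.3, 0.2, 0.25, 0.25),) * 3)
        t_total = 0.2
        tree = parse_newick(f"(A:{t_total},B:0);")
        aln = simulate_codon_alignment(
            tree, 50_000, kappa=kappa, omega=omega, codon_freqs=pi, seed=3
        )
        P = expm(gy94_matrix(kappa, omega, pi) * t_total)
        idx = {c: i for i, c in enumerate(CODONS)}
        a = np.array([idx[aln.sequence_of("B")[k : k + 3]] for k in range(0, 150_000, 3)])
        b = np.array([idx[aln.sequence_of("A")[k : k + 3]] for k in range(0, 150_000, 3)])
        # overall substitution probability (1 - sum pi_i P_ii) is the
        # sharpest scalar summary; compare observed vs expected
        p_change_exp = float(1.0 - (pi * np.diag(P)).sum())
        p_change_obs = float((a != b).mean())
        assert abs(p_change_obs - p_change_exp) < 0.01
        # per-start-codon agreement for the commonest codons
        for ci in np.argsort(pi)[-5:]:
            mask = a == ci
            stay_obs = (b[mask] == ci).mean()
            assert abs(stay_obs - P[ci, ci]) < 0.05

    def test_omega_rejected(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError):
            simulate_codon_alignment(tree, 100, omega=0.0)

    def test_reproducible(self):
        tree = parse_newick("((A:0.1,B:0.1):0.05,C:0.15);")
        a = simulate_codon_alignment(tree, 100, seed=9)
        b = simulate_codon_alignment(tree, 100, seed=9)
        assert a.sequences == b.sequences


class TestGeneLoss:
    def test_loss_removes_rows_and_updates_truth(self, small_benchmark):
        dataset, truth = small_benchmark
        gene = sorted(dataset.alignments)[0]
        n_before = dataset.alignments[gene].n_taxa
        taxa = dataset.alignments[gene].taxa[:2]
        inject_gene_loss(dataset, [gene], taxa)
        assert dataset.alignments[gene].n_taxa == n_before - 2
        assert set(taxa) <= truth.genes[gene].lost_taxa

    def test_loss_below_four_taxa_flags_unusable(self):
        cfg = BenchmarkConfig(
            n_taxa=6, n_genes=5, ndh_loss=False, rpl33_loss=False
        )
        dataset, truth = make_benchmark_dataset(cfg, seed=1)
        gene = sorted(dataset.alignments)[0]
        drop = dataset.alignments[gene].taxa[:3]
        inject_gene_loss(dataset, [gene], drop)
        assert not truth.genes[gene].usable

    def test_unknown_gene_and_taxon_rejected(self, small_benchmark):
        dataset, _ = small_benchmark
        gene = sorted(dataset.alignments)[0]
        with pytest.raises(ValueError, match="unknown gene"):
            inject_gene_loss(dataset, ["nope"], dataset.alignments[gene].taxa[:1])
        with pytest.raises(ValueError, match="unknown taxa"):
            inject_gene_loss(dataset, [gene], ["NOT_A_TAXON"])


class TestBenchmark:
    def test_default_shape(self):
        dataset, truth = make_benchmark_dataset(seed=5)
        assert len(dataset.alignments) == 76
        full = [a for a in dataset.alignments.values() if not truth.genes[a.name].lost_taxa]
        assert all(a.n_taxa == 26 for a in full)
        assert all(a.length % 3 == 0 for a in dataset.alignments.values())
        # planted loss mirrors the template: NDH clade loss + rpl33
        assert truth.genes["rpl33"].lost_taxa
        ndh_lost = {g for g, t in truth.genes.items() if t.group == "NDH" and t.lost_taxa}
        assert len(ndh_lost) == 11

    def test_same_seed_identical_fasta(self, tmp_path):
        for sub in ("a", "b"):
            ds, _ = make_benchmark_dataset(
                BenchmarkConfig(n_taxa=8, n_genes=6), seed=3
            )
            ds.write(tmp_path / sub)
        for f in sorted((tmp_path / "a" / "alignments").iterdir()):
            other = tmp_path / "b" / "alignments" / f.name
            assert f.read_bytes() == other.read_bytes()

    def test_rate_multiplier_drives_segregating_sites(self):
        from chloroscape.variation import segregating_sites

        dataset, truth = make_benchmark_dataset(
            BenchmarkConfig(n_taxa=12, n_genes=40, ndh_loss=False, rpl33_loss=False),
            seed=11,
        )
        r = []
        s_per_site = []
        for gene, aln in dataset.alignments.items():
            r.append(truth.genes[gene].rate_multiplier)
            s_per_site.append(segregating_sites(aln) / aln.length)
        rho = spearmanr(r, s_per_site).statistic
        assert rho > 0.7

    def test_derive_seed_stable_and_bounded(self):
        assert derive_seed(1, "msc") == derive_seed(1, "msc")
        assert derive_seed(1, "msc") != derive_seed(2, "msc")
        assert 0 <= derive_seed(123456, "anything") < 2**31
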